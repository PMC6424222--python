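import numpy as np
import pandas as pd
import pytest

from sdmkit import calibration, stats


class TestCorrect:
    def test_bonferroni(self):
        np.testing.assert_allclose(
            stats.correct([0.01] * 5, "bonferroni"), [0.05] * 5
        )

    def test_bh_hand_computed(self):
        # q_i = min over j>=i of p_j * n / j -> all 0.04 for (1..4)/100
        np.testing.assert_allclose(
            stats.correct([0.01, 0.02, 0.03, 0.04], "bh"), [0.04] * 4
        )

    def test_empty(self):
        assert stats.correct([], "bh").size == 0


class TestIterativeChisq:
    def test_identical_tables_report_nothing(self):
        a = pd.Series({"x": 100, "y": 200, "z": 300})
        res = stats.iterative_chisq(a, a.copy())
        assert res.significant == []

    def test_tripled_class_reported_first(self):
        a = pd.Series({"x": 1000, "y": 1000, "z": 1000})
        b = pd.Series({"x": 3000, "y": 1000, "z": 1000})
        res = stats.iterative_chisq(a, b)
        assert res.significant and res.significant[0][0] == "x"
        # verify against a direct marginal 2x2 test
        from scipy.stats import chi2_contingency

        _, p, _, _ = chi2_contingency(
            [[1000, 2000], [3000, 2000]], correction=False
        )
        assert res.significant[0][1] == pytest.approx(min(1.0, p * 3))

    def test_never_reports_marginally_nonsignificant_class(self):
        rng = np.random.default_rng(5)
        from scipy.stats import chi2_contingency

        for _ in range(20):
            a = pd.Series(rng.multinomial(5000, [0.2, 0.3, 0.5]), index=list("xyz"))
            b = pd.Series(rng.multinomial(5000, [0.25, 0.3, 0.45]), index=list("xyz"))
            res = stats.iterative_chisq(a, b, correction="bonferroni")
            for cls, p_adj in res.significant:
                assert p_adj < 0.05


class TestEnrichmentScreen:
    def test_equal_fractions_empty(self):
        counts = pd.DataFrame({"EUR": [500, 9500], "AFR": [500, 9500]},
                              index=["x", "rest"])
        assert stats.enrichment_screen(counts).empty

    def test_twofold_class_passes(self):
        # two-fold fraction difference with both counts above the 150 floor
        counts = pd.DataFrame(
            {"EUR": [600, 19400], "AFR": [300, 19700]}, index=["x", "rest"]
        )
        df = stats.enrichment_screen(counts)
        row = df[df["class"] == "x"].iloc[0]
        assert row["log2_ratio"] == pytest.approx(1.0, abs=0.05)
        assert row["p"] < 0.05

    def test_count_threshold_excludes_regardless_of_ratio(self):
        counts = pd.DataFrame(
            {"EUR": [149, 9851], "AFR": [40, 9960]}, index=["x", "rest"]
        )
        df = stats.enrichment_screen(counts)
        assert df.empty or "x" not in set(df["class"])


class TestFlowTable:
    def test_published_ttt_row_proportions(self):
        counts = pd.DataFrame(
            {
                "ancestral": ["TTT"] * 3,
                "derived": ["TAA", "TCA", "TGA"],
                "count": [1817, 81, 28],
            }
        )
        flow = stats.FlowTable.from_counts(counts, intermediate="TTA")
        assert flow.proportion("TTT", "TAA") == pytest.approx(0.94, abs=0.005)
        assert flow.proportion("TTT", "TCA") == pytest.approx(0.04, abs=0.005)
        assert flow.proportion("TTT", "TGA") == pytest.approx(0.01, abs=0.005)

    def test_row_sums_to_one(self):
        counts = pd.DataFrame(
            {
                "ancestral": ["TTG"] * 3,
                "derived": ["TAA", "TCA", "TGA"],
                "count": [44, 162, 49],
            }
        )
        flow = stats.FlowTable.from_counts(counts, intermediate="TTA")
        assert flow.table.groupby("ancestral")["proportion"].sum().iloc[0] == (
            pytest.approx(1.0)
        )
        assert flow.proportion("TTG", "TAA") == pytest.approx(0.17, abs=0.005)

    def test_single_path_proportion_one(self):
        from sdmkit.contexts import ChangeKey, SDMPath

        p = SDMPath(
            kind="noncoding", anchor="5p", ancestral="TTT", intermediate="TTA",
            derived="TAA", step1=ChangeKey("TTT", 3, "A"),
            step2=ChangeKey("TTA", 2, "A"), chrom="1", pos=0,
        )
        flow = stats.flow_proportions([p], "TTA")
        assert flow.proportion("TTT", "TAA") == 1.0


class TestAncestralDependence:
    def test_published_ttt_vs_ttg_highly_significant(self):
        counts = pd.DataFrame(
            {
                "ancestral": ["TTT"] * 3 + ["TTG"] * 3,
                "derived": ["TAA", "TCA", "TGA"] * 2,
                "count": [1817, 81, 28, 44, 162, 49],
            }
        )
        flow = stats.FlowTable.from_counts(counts, intermediate="TTA")
        chi2, p = stats.ancestral_dependence_test(flow, "TTT", "TTG")
        assert p < 1e-6

    def test_identical_rows_give_p_one(self):
        counts = pd.DataFrame(
            {
                "ancestral": ["A1"] * 2 + ["A2"] * 2,
                "derived": ["D1", "D2"] * 2,
                "count": [30, 70, 30, 70],
            }
        )
        flow = stats.FlowTable.from_counts(counts, intermediate="XXX")
        chi2, p = stats.ancestral_dependence_test(flow, "A1", "A2")
        assert chi2 == 0.0 and p == 1.0


class TestStrandAsymmetry:
    def test_identical_proportions_p_one(self):
        df = stats.strand_asymmetry(
            {("ACA", "ACG", "ATG"): 10, ("TGT", "CGT", "CAT"): 10},
            {"ACA": 1000, "TGT": 1000},
        )
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_planted_excess_ranked_first(self):
        counts = {
            ("ACA", "ACG", "ATG"): 300,
            ("TGT", "CGT", "CAT"): 100,
            ("AAA", "AAT", "ATT"): 50,
            ("AAT", "ATT", "AAT"): 48,
        }
        abundance = {"ACA": 2000, "TGT": 2000, "AAA": 2000, "AAT": 2000,
                     "ATT": 2000}
        df = stats.strand_asymmetry(counts, abundance, seed=0)
        assert df.iloc[0]["path"] == "ACA>ACG>ATG"
        assert df.iloc[0]["p"] < 1e-4
        assert df.iloc[0]["enriched"] == "ACA>ACG>ATG"

    def test_global_reverse_complement_invariance(self):
        counts = {("ACA", "ACG", "ATG"): 120, ("TGT", "CGT", "CAT"): 80}
        abundance = {"ACA": 1500, "TGT": 2500}
        fwd = stats.strand_asymmetry(counts, abundance, seed=0)
        rc_counts = {
            ("TGT", "CGT", "CAT"): 120, ("ACA", "ACG", "ATG"): 80,
        }
        rc_abund = {"TGT": 1500, "ACA": 2500}
        rev = stats.strand_asymmetry(rc_counts, rc_abund, seed=0)
        assert fwd["p"].iloc[0] == pytest.approx(rev["p"].iloc[0])


class TestSingleCodonContrast:
    def test_degenerate_indicator_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            stats.single_codon_contrast([1, 2], [1, 2], [False, False])

    def test_planted_enrichment_detected(self):
        ps = calibration.single_codon_pvalues(n_reps=5, enrichment=5.0, seed=1)
        assert (ps < 0.01).all()


class TestCpGInteraction:
    def test_degenerate_single_class_errors(self):
        df = pd.DataFrame(
            {
                "observed": [3, 4],
                "expected": [3.0, 4.0],
                "first_base_change": ["A>G", "A>G"],
                "cpg_change": ["none>none", "none>none"],
                "defined": True,
            }
        )
        with pytest.raises(ValueError, match="full rank"):
            stats.fit_cpg_interaction(df)

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(2)
        df = calibration._interaction_frame(rng, boost=10.0)
        res = stats.fit_cpg_interaction(df)
        assert res.anova_p < 0.01
        assert res.pseudo_r2 is not None


class TestCodingModels:
    def _table(self, rng, n=576, stop_depletion=1.0):
        baseline = rng.lognormal(3.0, 0.8, size=n)
        func = rng.choice(
            ["synonymous", "missense", "stop_gained"], size=n, p=[0.3, 0.6, 0.1]
        )
        cpg = rng.choice(calibration.CPG_LEVELS, size=n)
        mu = 2.0 * baseline * np.where(func == "stop_gained", stop_depletion, 1.0)
        counts = mu + rng.normal(0, 4.0, size=n)
        return pd.DataFrame(
            {
                "first_coding": counts,
                "coding_snp": baseline,
                "func_class": func,
                "cpg_change": cpg,
            }
        )

    def test_proportional_counts_give_null_func_coefficients(self):
        rng = np.random.default_rng(3)
        df = self._table(rng)
        res = stats.fit_coding_model(df, "first_coding", "coding_snp")
        func_ps = [p for k, p in res.pvalues.items() if "func_class" in k]
        assert min(func_ps) > 0.001  # no spurious strong signal

    def test_planted_stop_gained_depletion_detected(self):
        rng = np.random.default_rng(4)
        df = self._table(rng, stop_depletion=0.2)
        res = stats.fit_coding_model(df, "first_coding", "coding_snp")
        key = [k for k in res.params.index if "stop_gained" in k][0]
        assert res.params[key] < 0
        assert res.pvalues[key] < 0.01

    def test_missing_covariate_rows_excluded(self):
        rng = np.random.default_rng(5)
        df = self._table(rng)
        df["ratio"] = 1.0
        df.loc[df.index[0], "ratio"] = np.nan
        df["first_interg"] = df["coding_snp"]
        res = stats.fit_coding_model(
            df, "first_coding", "first_interg", use_ratio=True
        )
        assert len(res.residuals) == 575


class TestEpistasisModel:
    def test_non_missense_first_change_rejected(self):
        df = calibration._epistasis_frame(np.random.default_rng(0), n_classes=50)
        df.loc[df.index[0], "first_consequence"] = "synonymous"
        with pytest.raises(ValueError, match="non-missense"):
            stats.epistasis_model(df)

    def test_planted_deficit_negative_and_significant(self):
        df = calibration._epistasis_frame(
            np.random.default_rng(1), missense_deficit=0.4
        )
        res = stats.epistasis_model(df)
        assert res.contrast["missense_vs_synonymous_coef"] < 0
        assert res.contrast["missense_vs_synonymous_p"] < 0.05

    def test_ols_family_also_supported(self):
        df = calibration._epistasis_frame(
            np.random.default_rng(2), missense_deficit=0.4
        )
        res = stats.epistasis_model(df, family="ols")
        assert res.family == "ols"
        assert res.contrast["missense_vs_synonymous_coef"] < 0
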