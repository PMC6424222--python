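import numpy as np
import pandas as pd
import pytest

from sdmkit import caller, io, simulate


@pytest.fixture(scope="module")
def small_cohort():
    model = simulate.MutationModel(low_conf_fraction=0.05)
    return simulate.generate(
        model, genome_length=50_000, n_per_pop=10, seed=7, n_genes=2,
        gene_length=300,
    )


class TestDeterminism:
    def test_identical_seeds_byte_identical_outputs(self, tmp_path):
        model = simulate.MutationModel()
        out = []
        for d in ("a", "b"):
            cohort = simulate.generate(
                model, genome_length=20_000, n_per_pop=5, seed=11
            )
            paths = simulate.write_cohort(cohort, str(tmp_path / d))
            out.append(paths)
        for key in out[0]:
            with open(out[0][key], "rb") as f1, open(out[1][key], "rb") as f2:
                assert f1.read() == f2.read(), key


class TestRoundTrip:
    def test_write_then_ingest_identical_haplotypes(self, small_cohort, tmp_path):
        paths = simulate.write_cohort(small_cohort, str(tmp_path / "c"))
        variants, skipped = io.read_phased_variants(paths["vcf"])
        assert skipped == 0
        assert len(variants) == len(small_cohort.positions)
        anc = io.read_ancestral(paths["ancestral"])[small_cohort.chrom]
        polarized, rejections = io.polarize_all(
            variants, {small_cohort.chrom: anc}
        )
        # derived masks match the generator's haplotype matrix exactly
        by_pos = {v.pos: v for v in polarized}
        checked = 0
        for i, pos in enumerate(small_cohort.positions):
            v = by_pos.get(int(pos))
            if v is None:  # rejected (low-confidence ancestral)
                continue
            np.testing.assert_array_equal(
                v.derived_mask.astype(np.int8), small_cohort.haplotypes[i]
            )
            checked += 1
        assert checked > 100

    def test_panel_and_ledger_round_trip(self, small_cohort, tmp_path):
        paths = simulate.write_cohort(small_cohort, str(tmp_path / "c"))
        panel = io.read_panel(paths["panel"])
        assert panel.samples == small_cohort.sample_ids
        ledger = pd.read_csv(paths["ledger"], sep="\t")
        assert len(ledger) == len(small_cohort.ledger)

    def test_empty_cohort_writes_valid_files(self, tmp_path):
        model = simulate.MutationModel(
            transition_rate=0.0, transversion_rate=0.0, mnp_rate=0.0
        )
        cohort = simulate.generate(model, genome_length=5_000, n_per_pop=3, seed=0)
        assert len(cohort.positions) == 0
        paths = simulate.write_cohort(cohort, str(tmp_path / "e"))
        variants, skipped = io.read_phased_variants(paths["vcf"])
        assert variants == []


class TestLowConfidence:
    def test_polarize_rejects_about_planted_fraction(self, small_cohort):
        variants = small_cohort.to_phased_variants()
        _, rejections = io.polarize_all(
            variants, {small_cohort.chrom: small_cohort.ancestral_sequence()}
        )
        frac = rejections["low_confidence"] / len(variants)
        # planted 5%, binomial tolerance
        assert 0.03 < frac < 0.07


class TestGroundTruth:
    def test_every_derived_allele_traces_to_ledger(self, small_cohort):
        ledger_positions = set(small_cohort.ledger["pos1"]) | set(
            p for p in small_cohort.ledger["pos2"] if p >= 0
        )
        assert ledger_positions == set(int(p) for p in small_cohort.positions)

    def test_mnp_channel_enriched_for_polymerase_zeta_classes(self):
        model = simulate.MutationModel(mnp_rate=3e-3)
        cohort = simulate.generate(
            model, genome_length=600_000, n_per_pop=5, seed=13, n_genes=0
        )
        mnps = cohort.ledger[cohort.ledger["type"] == "mnp"]
        assert len(mnps) > 300
        ga = mnps[mnps["anc"] == "GA"]
        assert len(ga) > 50
        # the planted enrichment makes GA>TT the dominant GA outcome
        assert (ga["der"] == "TT").mean() > 0.5

    def test_strand_symmetric_snp_classes(self):
        """With strand-symmetric rates, complementary substitution classes
        are planted in statistically indistinguishable numbers."""
        from scipy.stats import chi2_contingency

        model = simulate.MutationModel()
        cohort = simulate.generate(
            model, genome_length=400_000, n_per_pop=5, seed=17, n_genes=0
        )
        snps = cohort.ledger[cohort.ledger["type"] == "snp"]
        subs = snps["anc"] + ">" + snps["der"]
        comp = str.maketrans("ACGT", "TGCA")
        pairs = {}
        for s, n in subs.value_counts().items():
            rc = s[0].translate(comp) + ">" + s[2].translate(comp)
            key = tuple(sorted([s, rc]))
            pairs.setdefault(key, []).append(n)
        table = np.array([v for v in pairs.values() if len(v) == 2])
        assert table.sum() > 1000
        _, p, _, _ = chi2_contingency(table.T)
        assert p > 0.05


class TestSwitchErrors:
    def test_rate_zero_is_identity(self, small_cohort):
        out = simulate.inject_switch_errors(small_cohort, 0.0, seed=1)
        assert out is small_cohort

    def test_rate_one_flips_downstream_phase(self):
        """With rate 1, phase toggles at every het site: the first het is
        swapped, the second swaps back, and so on."""
        model = simulate.MutationModel()
        cohort = simulate.generate(model, genome_length=20_000, n_per_pop=5, seed=3)
        flipped = simulate.inject_switch_errors(cohort, 1.0, seed=1)
        a, b = cohort.haplotypes[:, 0], cohort.haplotypes[:, 1]
        het = a != b
        fa, fb = flipped.haplotypes[:, 0], flipped.haplotypes[:, 1]
        parity = np.cumsum(het) % 2  # 1 after an odd number of toggles
        swapped = parity.astype(bool)
        np.testing.assert_array_equal(fa[swapped], b[swapped])
        np.testing.assert_array_equal(fa[~swapped], a[~swapped])

    def test_small_rate_degrades_few_calls(self):
        model = simulate.MutationModel()
        cohort = simulate.generate(
            model, genome_length=100_000, n_per_pop=10, seed=23, n_genes=0
        )
        noisy = simulate.inject_switch_errors(cohort, 0.0034, seed=5)

        def call(c):
            variants = c.to_phased_variants()
            polarized, _ = io.polarize_all(
                variants, {c.chrom: c.ancestral_sequence()}
            )
            cs = caller.call_sdms(polarized, c.panel)
            return {(x.pos, x.order) for x in cs.calls}

        clean, degraded = call(cohort), call(noisy)
        planted = {
            (row.pos1, row.order)
            for row in cohort.ledger[cohort.ledger["type"] == "sdm"].itertuples()
        }
        assert planted <= clean
        miscalled = len(planted - degraded) / max(len(planted), 1)
        assert miscalled < 0.1  # 0.34% switch errors barely move the calls
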