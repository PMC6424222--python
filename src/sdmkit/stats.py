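"""The statistical battery for SDM analyses.

Covers: iterative conditionally-independent chi-square spectrum comparisons,
the population enrichment screen, the CpG-interaction count model, the coding
regressions against intergenic-SDM and coding-SNP baselines, the single-codon
amino-acid contrast, flow-proportion tables with ancestral-state dependence
tests, coding-strand asymmetry, the epistasis model, and multiple-testing
corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .contexts import revcomp

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def correct(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment (values capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown correction {method!r}")


# ---------------------------------------------------------------------------
# iterative conditionally-independent chi-square
# ---------------------------------------------------------------------------


@dataclass
class SpectrumComparison:
    significant: list[tuple[str, float]]  # (class, adjusted p) in removal order
    steps: list[dict]
    stop_reason: str


def iterative_chisq(
    counts_a: pd.Series,
    counts_b: pd.Series,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> SpectrumComparison:
    """Compare two count spectra by peeling off the top-contributing class.

    At each step the class with the largest contribution to the overall 2xK
    chi-square is tested marginally (2x2, class vs rest) with the stated
    correction; if significant it is recorded, removed, and the procedure
    repeats on the reduced table.  Stops when the top class is non-significant
    or one class remains.  Classes whose expected cell falls below 1 are
    merged into an "other" bucket.
    """
    shared = counts_a.index.union(counts_b.index)
    a = counts_a.reindex(shared, fill_value=0).astype(float)
    b = counts_b.reindex(shared, fill_value=0).astype(float)
    k0 = len(shared)
    significant: list[tuple[str, float]] = []
    steps: list[dict] = []
    stop = "exhausted"
    while len(a) > 1:
        table = np.vstack([a.to_numpy(), b.to_numpy()])
        if table.sum() == 0:
            stop = "empty"
            break
        expected = sps.contingency.expected_freq(table)
        low = expected.min(axis=0) < 1
        if low.any() and (~low).sum() >= 1:
            other = pd.Index(a.index[low])
            a = pd.concat([a[~low], pd.Series({"other": a[low].sum()})])
            b = pd.concat([b[~low], pd.Series({"other": b[low].sum()})])
            log.info("merged %d low-expectation classes into 'other'", low.sum())
            continue
        contrib = (table - expected) ** 2 / np.where(expected > 0, expected, 1)
        per_class = contrib.sum(axis=0)
        top = int(np.argmax(per_class))
        cls = a.index[top]
        two_by_two = np.array(
            [
                [a.iloc[top], a.drop(a.index[top]).sum()],
                [b.iloc[top], b.drop(b.index[top]).sum()],
            ]
        )
        chi2, p, _, _ = sps.chi2_contingency(two_by_two, correction=False)
        p_adj = min(1.0, p * k0) if correction == "bonferroni" else p
        steps.append({"class": cls, "p": p, "p_adj": p_adj, "k": len(a)})
        if p_adj >= alpha:
            stop = "top class non-significant"
            break
        significant.append((cls, p_adj))
        a = a.drop(cls)
        b = b.drop(cls)
    else:
        stop = "single class remaining"
    return SpectrumComparison(significant=significant, steps=steps, stop_reason=stop)


# ---------------------------------------------------------------------------
# population enrichment screen
# ---------------------------------------------------------------------------


def enrichment_screen(
    counts_by_pop: pd.DataFrame,
    pair_list: Sequence[tuple[str, str]] | None = None,
    min_count: int = 150,
    min_log2: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-exact screen of class counts between population pairs.

    ``counts_by_pop``: classes x populations.  A class is reported only when
    it has at least ``min_count`` sites in each population of a comparison,
    |log2 ratio| >= ``min_log2``, and Fisher p < alpha in >= 1 comparison.
    BH q-values are computed per population pair across all tested classes.
    """
    pops = list(counts_by_pop.columns)
    if pair_list is None:
        pair_list = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]
    totals = counts_by_pop.sum(axis=0)
    rows = []
    for pa, pb in pair_list:
        ca, cb = counts_by_pop[pa], counts_by_pop[pb]
        ps = []
        kept = []
        for cls in counts_by_pop.index:
            x, y = int(ca[cls]), int(cb[cls])
            table = [[x, int(totals[pa]) - x], [y, int(totals[pb]) - y]]
            _, p = sps.fisher_exact(table)
            with np.errstate(divide="ignore", invalid="ignore"):
                l2 = np.log2((x / totals[pa]) / (y / totals[pb])) if x and y else np.nan
            kept.append((cls, x, y, l2))
            ps.append(p)
        qs = correct(ps, "bh")
        for (cls, x, y, l2), p, q in zip(kept, ps, qs):
            rows.append(
                {
                    "class": cls,
                    "pop_a": pa,
                    "pop_b": pb,
                    "count_a": x,
                    "count_b": y,
                    "log2_ratio": l2,
                    "p": p,
                    "q": q,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    passes = (
        (df["count_a"] >= min_count)
        & (df["count_b"] >= min_count)
        & (df["log2_ratio"].abs() >= min_log2)
        & (df["p"] < alpha)
    )
    keep_classes = df.loc[passes, "class"].unique()
    return df[df["class"].isin(keep_classes)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    family: str
    params: pd.Series
    pvalues: pd.Series
    llf: float
    pseudo_r2: float | None = None
    anova_p: float | None = None
    contrast: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    residuals: pd.Series | None = None


def _estimate_nb_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Moment estimator of the NB2 dispersion: var = mu + alpha mu^2."""
    mask = mu > 0
    aux = ((y[mask] - mu[mask]) ** 2 - y[mask]) / mu[mask]
    denom = float(np.sum(mu[mask] ** 2))
    if denom == 0:
        return 0.0
    return float(np.sum(aux * mu[mask])) / denom


def _design_matrices(
    df: pd.DataFrame, formula: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build response/design matrices, pruning empty and collinear columns.

    Interaction designs over sparse class tables routinely contain cells with
    no observations (impossible substitution x CpG-effect combinations);
    QR column pivoting keeps a maximal independent column subset so the GLM
    stays estimable.  The intercept is always retained.
    """
    import patsy
    from scipy.linalg import qr

    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    X = X.loc[:, (X != 0).any(axis=0)]
    arr = X.to_numpy()
    _, R, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0:
        raise ValueError("design not full rank")
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    return y, X.iloc[:, keep]


def fit_cpg_interaction(records, family: str = "auto") -> RegressionResult:
    """Count model of observed SDM counts with a change x CpG interaction.

    obs ~ expected + firstBaseChange + cpgChange + firstBaseChange:cpgChange,
    fit as a negative-binomial GLM (dispersion estimated by moments from a
    Poisson fit; Poisson fallback when no over-dispersion).  The interaction
    is assessed by a likelihood-ratio ANOVA against the model without it.
    """
    if not isinstance(records, pd.DataFrame):
        from .expectation import records_to_frame

        records = records_to_frame(records)
    df = records.dropna(subset=["expected"])
    df = df[df["defined"]] if "defined" in df else df
    df = df[df["expected"] > 0].copy()
    df["observed"] = df["observed"].astype(float)
    if df["first_base_change"].nunique() < 2 or df["cpg_change"].nunique() < 2:
        raise ValueError("design not full rank")
    full_f = "observed ~ np.log(expected) + C(first_base_change) * C(cpg_change)"
    red_f = "observed ~ np.log(expected) + C(first_base_change) + C(cpg_change)"
    y_full, X_full = _design_matrices(df, full_f)
    y_red, X_red = _design_matrices(df, red_f)
    yv = y_full.to_numpy().ravel()
    pois = sm.GLM(y_full, X_full, family=sm.families.Poisson()).fit()
    alpha = max(_estimate_nb_alpha(yv, np.asarray(pois.fittedvalues)), 0.0)
    notes = []
    if alpha > 1e-6 and family != "poisson":
        # iterate the moment estimator against NB fitted means
        for _ in range(2):
            m = sm.GLM(
                y_full, X_full, family=sm.families.NegativeBinomial(alpha=alpha)
            ).fit(maxiter=200)
            alpha = max(_estimate_nb_alpha(yv, np.asarray(m.fittedvalues)), 1e-6)
    if family == "poisson" or alpha <= 1e-6:
        fam = sm.families.Poisson()
        fam_name = "poisson"
        if family == "auto" and alpha <= 1e-6:
            notes.append("no over-dispersion detected; Poisson used")
    else:
        fam = sm.families.NegativeBinomial(alpha=alpha)
        fam_name = f"negative_binomial(alpha={alpha:.4g})"

    def _fit(fam):
        full = sm.GLM(y_full, X_full, family=fam).fit(maxiter=200)
        reduced = sm.GLM(y_red, X_red, family=fam).fit(maxiter=200)
        return full, reduced

    try:
        full, reduced = _fit(fam)
    except Exception:  # non-convergence of the NB fit
        fam = sm.families.Poisson()
        fam_name = "poisson"
        notes.append(f"NB fit failed; Poisson fallback (overdispersion alpha={alpha:.3g})")
        full, reduced = _fit(fam)
    # deviance F-test for the interaction block; the Pearson scale of the
    # full model absorbs residual dispersion misestimation
    df_diff = X_full.shape[1] - X_red.shape[1]
    if df_diff > 0 and full.df_resid > 0:
        phi = full.pearson_chi2 / full.df_resid
        fstat = (reduced.deviance - full.deviance) / (df_diff * phi)
        anova_p = float(sps.f.sf(max(fstat, 0.0), df_diff, full.df_resid))
    else:
        anova_p = float("nan")
    null = sm.GLM(y_full, np.ones((len(y_full), 1)), family=fam).fit()
    pseudo = 1 - full.llf / null.llf if null.llf != 0 else np.nan
    return RegressionResult(
        family=fam_name,
        params=full.params,
        pvalues=full.pvalues,
        llf=full.llf,
        pseudo_r2=pseudo,
        anova_p=anova_p,
        notes=notes,
    )


def fit_coding_model(
    df: pd.DataFrame,
    count_col: str,
    baseline_col: str,
    use_ratio: bool = False,
) -> RegressionResult:
    """One linear model of per-codon-change counts against a baseline.

    count ~ baseline [+ ratio] + funcClass + cpgChange + funcClass:cpgChange,
    ordinary least squares; standardized residuals returned for outlier
    labelling.
    """
    cols = [count_col, baseline_col, "func_class", "cpg_change"]
    if use_ratio:
        cols.append("ratio")
    data = df.dropna(subset=cols).copy()
    excluded = len(df) - len(data)
    if excluded:
        log.info("%d classes excluded from %s model (missing covariates)",
                 excluded, count_col)
    terms = [baseline_col] + (["ratio"] if use_ratio else [])
    formula = (
        f"{count_col} ~ " + " + ".join(terms)
        + " + C(func_class) * C(cpg_change)"
    )
    res = smf.ols(formula, data).fit()
    infl = res.get_influence()
    std_resid = pd.Series(infl.resid_studentized_internal, index=data.index)
    return RegressionResult(
        family="ols",
        params=res.params,
        pvalues=res.pvalues,
        llf=res.llf,
        pseudo_r2=res.rsquared,
        residuals=std_resid,
    )


def fit_coding_models(table: pd.DataFrame) -> dict[str, RegressionResult]:
    """The four coding regressions (first/second x intergenic/coding-SNP).

    ``table`` is indexed by the 576 codon-change classes with columns
    first_coding, second_coding, first_interg, second_interg, coding_snp,
    ratio, func_class, cpg_change.
    """
    return {
        "first_vs_intergenic": fit_coding_model(
            table, "first_coding", "first_interg", use_ratio=True
        ),
        "first_vs_coding_snp": fit_coding_model(table, "first_coding", "coding_snp"),
        "second_vs_intergenic": fit_coding_model(
            table, "second_coding", "second_interg", use_ratio=True
        ),
        "second_vs_coding_snp": fit_coding_model(table, "second_coding", "coding_snp"),
    }


def single_codon_contrast(
    observed: Sequence[float],
    expected: Sequence[float],
    single_codon: Sequence[bool],
) -> RegressionResult:
    """Logistic contrast of single-codon-creating changes versus the rest.

    Per class, observed and expected counts form a binomial response; the
    single-codon indicator (derived codon ATG or TGG) is the lone covariate.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    ind = np.asarray(single_codon, dtype=float)
    if ind.sum() == 0 or ind.sum() == len(ind):
        raise ValueError("degenerate contrast")
    keep = (obs + exp) > 0
    endog = np.column_stack([obs[keep], exp[keep]])
    exog = sm.add_constant(ind[keep])
    res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    return RegressionResult(
        family="binomial",
        params=pd.Series(res.params, index=["intercept", "single_codon"]),
        pvalues=pd.Series(res.pvalues, index=["intercept", "single_codon"]),
        llf=res.llf,
        contrast={"single_codon_p": float(res.pvalues[1]),
                  "single_codon_coef": float(res.params[1])},
    )


# ---------------------------------------------------------------------------
# flow proportions and ancestral-state dependence
# ---------------------------------------------------------------------------


@dataclass
class FlowTable:
    """Counts of SDMs through one intermediate triplet, by ancestral and
    derived triplet, with within-ancestral-row proportions."""

    intermediate: str
    region: str
    table: pd.DataFrame  # columns: ancestral, derived, count, proportion

    @classmethod
    def from_counts(
        cls, counts: pd.DataFrame, intermediate: str, region: str = "intergenic"
    ) -> "FlowTable":
        """``counts`` needs columns ancestral, derived, count."""
        df = counts.copy()
        totals = df.groupby("ancestral")["count"].transform("sum")
        df["proportion"] = df["count"] / totals
        return cls(intermediate=intermediate, region=region, table=df)

    def row(self, ancestral: str) -> pd.Series:
        sub = self.table[self.table["ancestral"] == ancestral]
        return sub.set_index("derived")["count"]

    def proportion(self, ancestral: str, derived: str) -> float:
        sub = self.table[
            (self.table["ancestral"] == ancestral) & (self.table["derived"] == derived)
        ]
        if sub.empty:
            raise KeyError(f"{ancestral}->{derived} not in flow table")
        return float(sub["proportion"].iloc[0])


def flow_proportions(
    paths: Iterable, intermediate: str, region: str = "intergenic"
) -> FlowTable:
    """Build a FlowTable from ordered SDM path records."""
    counts: dict[tuple[str, str], int] = {}
    for p in paths:
        if p.intermediate != intermediate:
            continue
        key = (p.ancestral, p.derived)
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        [{"ancestral": a, "derived": d, "count": c} for (a, d), c in sorted(counts.items())]
    )
    if df.empty:
        df = pd.DataFrame(columns=["ancestral", "derived", "count"])
    return FlowTable.from_counts(df, intermediate, region)


def ancestral_dependence_test(
    flow: FlowTable, anc_a: str, anc_b: str
) -> tuple[float, float]:
    """Chi-square test of derived-triplet distributions for two ancestral
    states sharing the flow table's intermediate triplet.

    Returns (statistic, p).  Derived classes whose expected count falls below
    1 are pooled (logged).
    """
    ra = flow.row(anc_a)
    rb = flow.row(anc_b)
    derived = ra.index.union(rb.index)
    if len(derived) < 2:
        raise ValueError("need >= 2 derived classes")
    a = ra.reindex(derived, fill_value=0).to_numpy(dtype=float)
    b = rb.reindex(derived, fill_value=0).to_numpy(dtype=float)
    while True:
        table = np.vstack([a, b])
        expected = sps.contingency.expected_freq(table)
        low = expected.min(axis=0) < 1
        if not low.any() or len(a) <= 2:
            break
        log.info("pooling %d low-expectation derived classes", int(low.sum()))
        a = np.append(a[~low], a[low].sum())
        b = np.append(b[~low], b[low].sum())
    if np.array_equal(a / a.sum(), b / b.sum()):
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# strand asymmetry
# ---------------------------------------------------------------------------


def strand_asymmetry(
    coding_counts: dict[tuple[str, str, str], int],
    codon_abundance: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Coding-strand asymmetry between each SDM path and its reverse
    complement.

    For a pair, a 2x2 table of (SDM count, matching ancestral-codon count on
    the coding strand) is tested with Fisher's exact test.  Rows are ranked
    by p; the 'enriched' member is the one with the higher per-codon rate
    (ties broken by a seeded random draw).  Pairs whose ancestral codon has
    zero abundance are skipped.
    """
    rng = np.random.default_rng(seed)
    seen = set()
    rows = []
    for path, count in coding_counts.items():
        rc = tuple(revcomp(t) for t in path)
        if path in seen or rc in seen:
            continue
        seen.add(path)
        seen.add(rc)
        count_rc = coding_counts.get(rc, 0)
        anc, anc_rc = path[0], rc[0]
        ab = codon_abundance.get(anc, 0)
        ab_rc = codon_abundance.get(anc_rc, 0)
        if ab == 0 or ab_rc == 0:
            log.warning("pair %s/%s skipped: zero codon abundance", anc, anc_rc)
            continue
        table = [[count, ab - count], [count_rc, ab_rc - count_rc]]
        _, p = sps.fisher_exact(table)
        rate, rate_rc = count / ab, count_rc / ab_rc
        if rate > rate_rc:
            enriched = path
        elif rate_rc > rate:
            enriched = rc
        else:
            enriched = path if rng.random() < 0.5 else rc
        rows.append(
            {
                "path": ">".join(path),
                "revcomp_path": ">".join(rc),
                "count": count,
                "count_revcomp": count_rc,
                "abundance": ab,
                "abundance_revcomp": ab_rc,
                "enriched": ">".join(enriched),
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values("p").reset_index(drop=True)


# ---------------------------------------------------------------------------
# epistasis model
# ---------------------------------------------------------------------------


def epistasis_model(records: pd.DataFrame, family: str = "poisson") -> RegressionResult:
    """Count model for epistatic selection on missense-first coding SDMs.

    coding_count ~ interg_count + funcClass2 + codonCount + cpgChange1
    + cpgChange2, with funcClass2's missense-vs-synonymous contrast reported.
    ``family`` is "poisson" (default) or "ols".
    """
    required = {"coding_count", "interg_count", "func_class2", "codon_count",
                "cpg_change1", "cpg_change2"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    if "first_consequence" in records.columns:
        bad = records["first_consequence"] != "missense"
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} records have a non-missense first change"
            )
    df = records.copy()
    # the intergenic baseline enters on the log scale, matching the count
    # model's log link (coding counts proportional to intergenic counts)
    formula = (
        "coding_count ~ np.log(interg_count + 1.0) "
        "+ C(func_class2, Treatment(reference='synonymous')) "
        "+ codon_count + C(cpg_change1) + C(cpg_change2)"
    )
    if "intermediate_state" in df.columns:
        formula += " + C(intermediate_state)"
    if family == "poisson":
        res = smf.glm(formula, df, family=sm.families.Poisson()).fit()
        gof_p = float(sps.chi2.sf(res.deviance, res.df_resid))
        llf = res.llf
        null = smf.glm("coding_count ~ 1", df, family=sm.families.Poisson()).fit()
        pseudo = 1 - res.llf / null.llf if null.llf != 0 else np.nan
    elif family == "ols":
        res = smf.ols(formula, df).fit()
        gof_p = np.nan
        llf = res.llf
        pseudo = res.rsquared
    else:
        raise ValueError(f"unknown family {family!r}")
    key = "C(func_class2, Treatment(reference='synonymous'))[T.missense]"
    level_ps = {
        name: float(p)
        for name, p in res.pvalues.items()
        if name.startswith("C(func_class2")
    }
    qs = correct(list(level_ps.values()), "bh")
    q_map = dict(zip(level_ps, qs))
    contrast = {
        "missense_vs_synonymous_coef": float(res.params.get(key, np.nan)),
        "missense_vs_synonymous_p": float(res.pvalues.get(key, np.nan)),
        "missense_vs_synonymous_q": float(q_map.get(key, np.nan)),
        "goodness_of_fit_p": gof_p,
    }
    return RegressionResult(
        family=family,
        params=res.params,
        pvalues=res.pvalues,
        llf=llf,
        pseudo_r2=pseudo,
        contrast=contrast,
    )
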