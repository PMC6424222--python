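"""Monte-Carlo operating characteristics of the statistical battery.

Each statistical test has a matching null simulator that draws data at the
summary level the test consumes (multinomial spectra, count-model class
tables, binomial strand counts), runs the test, and collects its p-value.
Under the null the p-values should be uniform; planted-effect variants of the
same simulators are used for power checks.  Simulation sizes default to the
order of magnitude seen in population-scale SDM catalogues (tens of
thousands of sites spread over tens of classes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as st

CPG_LEVELS = ["none>none", "creates_cpg>destroys_cpg", "creates_cpg>none",
              "none>destroys_cpg"]
SUBS = ["A>C", "A>G", "A>T", "C>A", "C>G", "C>T",
        "G>A", "G>C", "G>T", "T>A", "T>C", "T>G"]


def ks_uniform_p(pvals) -> float:
    """KS test of p-values against U(0,1)."""
    return float(sps.kstest(np.asarray(pvals, dtype=float), "uniform").pvalue)


# ---------------------------------------------------------------------------
# iterative chi-square: family-wise error under the null
# ---------------------------------------------------------------------------


def iterative_chisq_fwer(
    n_reps: int = 1000, n_classes: int = 24, n_sites: int = 20_000,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Fraction of null replicates in which any class is reported."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(n_classes, 5.0))
    hits = 0
    idx = pd.Index([f"c{i}" for i in range(n_classes)])
    for _ in range(n_reps):
        a = pd.Series(rng.multinomial(n_sites, probs), index=idx)
        b = pd.Series(rng.multinomial(n_sites, probs), index=idx)
        res = st.iterative_chisq(a, b, alpha=alpha, correction="bonferroni")
        if res.significant:
            hits += 1
    return hits / n_reps


# ---------------------------------------------------------------------------
# enrichment screen / Fisher comparisons
# ---------------------------------------------------------------------------


def null_fisher_pvalues(
    n_reps: int = 200, n_classes: int = 20, n_sites: int = 20_000, seed: int = 0
) -> np.ndarray:
    """Fisher p for one fixed class under equal population fractions."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(n_classes, 10.0))
    out = np.empty(n_reps)
    for i in range(n_reps):
        a = rng.multinomial(n_sites, probs)
        b = rng.multinomial(n_sites, probs)
        table = [[a[0], a.sum() - a[0]], [b[0], b.sum() - b[0]]]
        out[i] = sps.fisher_exact(table)[1]
    return out


# ---------------------------------------------------------------------------
# CpG interaction model
# ---------------------------------------------------------------------------


def _interaction_frame(
    rng: np.random.Generator,
    n_classes: int = 2304,
    nb_alpha: float = 0.05,
    boost: float = 1.0,
) -> pd.DataFrame:
    """A class table of expected counts plus NB-noised observed counts.

    ``boost`` multiplies the mean of classes with first change A>G and CpG
    label creates_cpg>destroys_cpg (the planted interaction).
    """
    expected = rng.lognormal(mean=3.0, sigma=1.0, size=n_classes)
    fbc = rng.choice(SUBS, size=n_classes)
    cpg = rng.choice(CPG_LEVELS, size=n_classes, p=[0.55, 0.15, 0.15, 0.15])
    mu = expected.copy()
    planted = (fbc == "A>G") & (cpg == "creates_cpg>destroys_cpg")
    mu[planted] *= boost
    # NB2 draw: gamma-poisson mixture
    shape = 1.0 / nb_alpha
    lam = rng.gamma(shape, mu / shape)
    obs = rng.poisson(lam)
    return pd.DataFrame(
        {
            "observed": obs,
            "expected": expected,
            "first_base_change": fbc,
            "cpg_change": cpg,
            "defined": True,
        }
    )


def cpg_interaction_pvalues(
    n_reps: int = 200, n_classes: int = 2304, boost: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Interaction ANOVA p-values over replicates (boost=1 is the null)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        df = _interaction_frame(rng, n_classes=n_classes, boost=boost)
        out[i] = st.fit_cpg_interaction(df).anova_p
    return out


# ---------------------------------------------------------------------------
# coding linear models
# ---------------------------------------------------------------------------


def coding_model_pvalues(
    n_reps: int = 200, n_classes: int = 576, seed: int = 0
) -> np.ndarray:
    """p-value of one funcClass level when counts track the baseline.

    Counts are the baseline plus Gaussian noise (the linear model's own
    null), so the functional-class coefficients are zero in truth.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    classes = ["synonymous", "missense", "stop_gained"]
    for i in range(n_reps):
        baseline = rng.lognormal(3.0, 0.8, size=n_classes)
        func = rng.choice(classes, size=n_classes, p=[0.3, 0.6, 0.1])
        cpg = rng.choice(CPG_LEVELS, size=n_classes)
        counts = 2.0 * baseline + rng.normal(0, 5.0, size=n_classes)
        df = pd.DataFrame(
            {
                "first_coding": counts,
                "coding_snp": baseline,
                "func_class": func,
                "cpg_change": cpg,
            }
        )
        res = st.fit_coding_model(df, "first_coding", "coding_snp")
        key = [k for k in res.pvalues.index if "func_class" in k][0]
        out[i] = res.pvalues[key]
    return out


# ---------------------------------------------------------------------------
# single-codon contrast
# ---------------------------------------------------------------------------


def single_codon_pvalues(
    n_reps: int = 200, n_classes: int = 576, enrichment: float = 1.0, seed: int = 0
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        mu = rng.lognormal(2.5, 0.9, size=n_classes)
        ind = rng.random(n_classes) < 0.05
        # both columns are counts in the real pipeline, so both carry noise
        expected = rng.poisson(mu)
        obs = rng.poisson(mu * np.where(ind, enrichment, 1.0))
        res = st.single_codon_contrast(obs, expected, ind)
        out[i] = res.contrast["single_codon_p"]
    return out


# ---------------------------------------------------------------------------
# ancestral-state dependence
# ---------------------------------------------------------------------------


def ancestral_dependence_pvalues(
    n_reps: int = 200, n_derived: int = 3, n_sites: int = 2_000, seed: int = 0
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(n_derived, 8.0))
    out = np.empty(n_reps)
    derived = [f"D{i}" for i in range(n_derived)]
    for i in range(n_reps):
        a = rng.multinomial(n_sites, probs)
        b = rng.multinomial(n_sites, probs)
        counts = pd.DataFrame(
            {
                "ancestral": ["A1"] * n_derived + ["A2"] * n_derived,
                "derived": derived * 2,
                "count": np.concatenate([a, b]),
            }
        )
        flow = st.FlowTable.from_counts(counts, intermediate="XXX")
        out[i] = st.ancestral_dependence_test(flow, "A1", "A2")[1]
    return out


# ---------------------------------------------------------------------------
# strand asymmetry
# ---------------------------------------------------------------------------


def strand_asymmetry_pvalues(
    n_reps: int = 200, abundance: int = 20_000, rate: float = 0.02,
    excess: float = 1.0, seed: int = 0,
) -> np.ndarray:
    """Fisher p for one SDM/reverse-complement pair; excess=1 is the null."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    pair = ("ACA", "ACG", "ATG")
    rc = ("TGT", "CGT", "CAT")
    for i in range(n_reps):
        c1 = rng.binomial(abundance, min(1.0, rate * excess))
        c2 = rng.binomial(abundance, rate)
        df = st.strand_asymmetry(
            {pair: int(c1), rc: int(c2)},
            {pair[0]: abundance, rc[0]: abundance},
            seed=i,
        )
        out[i] = df["p"].iloc[0]
    return out


# ---------------------------------------------------------------------------
# epistasis model
# ---------------------------------------------------------------------------


def _epistasis_frame(
    rng: np.random.Generator, n_classes: int = 663, missense_deficit: float = 0.0
) -> pd.DataFrame:
    """Missense-first SDM class table with Poisson counts.

    ``missense_deficit`` is the fractional reduction of missense-second
    classes relative to synonymous-second (0 = null; 0.4 = planted 40%
    deficit).
    """
    interg = rng.lognormal(2.0, 1.0, size=n_classes)
    func2 = rng.choice(["synonymous", "missense", "stop_gained"],
                       size=n_classes, p=[0.35, 0.55, 0.10])
    codon_count = rng.integers(1, 7, size=n_classes)
    cpg1 = rng.choice(CPG_LEVELS, size=n_classes)
    cpg2 = rng.choice(CPG_LEVELS, size=n_classes)
    mu = 0.8 * interg * (1.05 ** codon_count)
    mu = mu * np.where(func2 == "missense", 1.0 - missense_deficit, 1.0)
    coding = rng.poisson(mu)
    return pd.DataFrame(
        {
            "coding_count": coding,
            "interg_count": interg,
            "func_class2": func2,
            "codon_count": codon_count,
            "cpg_change1": cpg1,
            "cpg_change2": cpg2,
            "first_consequence": "missense",
        }
    )


def epistasis_pvalues(
    n_reps: int = 200, n_classes: int = 663, missense_deficit: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Missense-vs-synonymous contrast p and sign over replicates."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        df = _epistasis_frame(rng, n_classes=n_classes,
                              missense_deficit=missense_deficit)
        res = st.epistasis_model(df)
        rows.append(
            {
                "p": res.contrast["missense_vs_synonymous_p"],
                "coef": res.contrast["missense_vs_synonymous_coef"],
            }
        )
    return pd.DataFrame(rows)
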