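"""Mutational fractions per change class and per population, and PCA.

The mutational fraction of a change class m in a population p is
C_p(m) / sum_m' C_p(m'), where C_p(m) counts the distinct polymorphic sites
of class m segregating (>= 1 carrier) in p.  Per-individual matrices instead
use carrier status: each individual's row is the fraction of the changes they
carry that fall in each class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .caller import CallSet, carrier_mask
from .contexts import SDMPath
from .io import PopulationPanel


@dataclass
class FractionTable:
    """Counts and normalized fractions per change class per population."""

    counts: pd.DataFrame  # index: class label; columns: populations
    role: str = "snp"

    @property
    def fractions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / totals

    def classes(self) -> list[str]:
        return list(self.counts.index)


def fraction_table(
    class_pop_pairs: Iterable[tuple[str, str]],
    role: str = "snp",
    populations: Sequence[str] | None = None,
) -> FractionTable:
    """Tabulate (class label, population) observations into a FractionTable.

    Each pair should appear once per distinct site per population where the
    site segregates.
    """
    rows: dict[str, dict[str, int]] = {}
    pops = set(populations or [])
    for cls, pop in class_pop_pairs:
        rows.setdefault(cls, {})
        rows[cls][pop] = rows[cls].get(pop, 0) + 1
        pops.add(pop)
    cols = sorted(pops)
    df = pd.DataFrame(
        [[rows.get(c, {}).get(p, 0) for p in cols] for c in sorted(rows)],
        index=sorted(rows),
        columns=cols,
        dtype=int,
    )
    return FractionTable(df, role=role)


def first_second_split(
    paths: Iterable[SDMPath], population: str = "ALL"
) -> tuple[FractionTable, FractionTable]:
    """Split ordered SDM paths into first-change and second-change spectra."""
    paths_list = list(paths)
    first = fraction_table(
        ((p.step1.label(), population) for p in paths_list), role="sdm_first"
    )
    second = fraction_table(
        ((p.step2.label(), population) for p in paths_list), role="sdm_second"
    )
    return first, second


def log2_ratio_table(a: FractionTable, b: FractionTable) -> pd.Series:
    """log2(fraction in a / fraction in b) over the shared class set."""
    fa = a.fractions.sum(axis=1)
    fb = b.fractions.sum(axis=1)
    shared = fa.index.union(fb.index)
    fa = fa.reindex(shared, fill_value=0.0)
    fb = fb.reindex(shared, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(fa / fb)


def individual_matrix(
    callset: CallSet,
    class_of: Callable,
    panel: PopulationPanel,
    per_haplotype: bool = False,
) -> pd.DataFrame:
    """Per-individual mutational-fraction matrix over carried SDMs.

    ``class_of(call) -> str`` chooses the class label (e.g. the first-change
    ChangeKey label or the full path label).  Rows are individuals (labelled
    with their population); individuals carrying nothing are dropped.  By
    default each SDM counts once per carrier individual; with
    ``per_haplotype`` it counts once per carrying haplotype instead.
    """
    if not callset.calls:
        return pd.DataFrame()
    samples = callset.calls[0].left.sample_ids
    counts: dict[str, np.ndarray] = {}
    for call in callset.calls:
        cls = class_of(call)
        if cls is None:
            continue
        vec = counts.setdefault(cls, np.zeros(len(samples)))
        if per_haplotype:
            dd = call.dd_mask.astype(int)
            vec += dd[0 : 2 * len(samples) : 2] + dd[1 : 2 * len(samples) : 2]
        else:
            vec += carrier_mask(call)
    mat = pd.DataFrame(counts, index=list(samples))
    totals = mat.sum(axis=1)
    kept = mat.loc[totals > 0]
    frac = kept.div(kept.sum(axis=1), axis=0)
    frac.insert(0, "population", [panel.group(s) for s in frac.index])
    return frac


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # rows: individuals; cols: PC1..PCk
    loadings: pd.DataFrame  # rows: classes; cols: PC1..PCk
    explained_variance_ratio: np.ndarray
    labels: pd.Series | None = None


def pca(matrix: pd.DataFrame, k: int = 2) -> PCAResult:
    """Column-centered PCA of an individual-spectrum matrix.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making coordinates reproducible across runs.
    """
    labels = None
    data = matrix
    if "population" in matrix.columns:
        labels = matrix["population"]
        data = matrix.drop(columns=["population"])
    X = data.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if k > max(rank, 1):
        raise ValueError(f"k={k} exceeds centered matrix rank {rank}")
    model = PCA(n_components=k)
    coords = model.fit_transform(X)  # sklearn centers columns internally
    components = model.components_
    for i in range(k):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1
            coords[:, i] *= -1
    names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=data.index, columns=names),
        loadings=pd.DataFrame(components.T, index=data.columns, columns=names),
        explained_variance_ratio=model.explained_variance_ratio_,
        labels=labels,
    )
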