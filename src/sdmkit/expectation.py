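"""Expected SDM frequencies from SNP rates, and intergenic -> coding scaling.

The probability of observing an ordered two-step path is modelled as

    P(change1 then change2) = P(change1) * P(change2 | change1)

where P(change1) is the mutational fraction of the first change among
(intergenic) SNPs in triplet context, and P(change2 | change1) is the count of
SNPs matching the second change divided by the count of all SNPs whose
ancestral triplet is the intermediate triplet created by change1 and whose
mutated position differs from change1's.  Expected counts are reported both
as probabilities and scaled so expected totals match an observed total.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contexts import BASES, ChangeKey, CpGEffect, cpg_effect

log = logging.getLogger(__name__)


class TripletPath(tuple):
    """(ancestral triplet, pos1, derived1, pos2, derived2); both positions
    1-based within the triplet and adjacent to each other."""

    __slots__ = ()

    def __new__(cls, anc, pos1, d1, pos2, d2):
        return super().__new__(cls, (anc, pos1, d1, pos2, d2))

    @property
    def ancestral(self):
        return self[0]

    @property
    def step1(self) -> ChangeKey:
        return ChangeKey(self[0], self[1], self[2])

    @property
    def intermediate(self):
        return self.step1.derived_triplet

    @property
    def step2(self) -> ChangeKey:
        return ChangeKey(self.intermediate, self[3], self[4])

    @property
    def derived(self):
        return self.step2.derived_triplet

    @property
    def label(self):
        return f"{self.ancestral}>{self.intermediate}>{self.derived}"

    @property
    def dinuc_core(self) -> tuple[str, str, str]:
        """(anc, inter, der) restricted to the two mutated positions."""
        lo = min(self[1], self[3]) - 1
        hi = lo + 2
        return (self.ancestral[lo:hi], self.intermediate[lo:hi], self.derived[lo:hi])


def enumerate_path_classes() -> list[TripletPath]:
    """All ordered two-step paths within a triplet at adjacent positions."""
    out = []
    pairs = [(1, 2), (2, 1), (2, 3), (3, 2)]
    for anc in ("".join(p) for p in itertools.product(BASES, repeat=3)):
        for pos1, pos2 in pairs:
            for d1 in BASES:
                if d1 == anc[pos1 - 1]:
                    continue
                inter = anc[: pos1 - 1] + d1 + anc[pos1:]
                for d2 in BASES:
                    if d2 == inter[pos2 - 1]:
                        continue
                    out.append(TripletPath(anc, pos1, d1, pos2, d2))
    return out


@dataclass
class ConditionalExpectation:
    path: TripletPath
    p_change1: float
    p_change2_given_1: float
    p_joint: float
    defined: bool = True


def conditional_probability(
    change1: ChangeKey, change2: ChangeKey, snp_counts: dict[ChangeKey, float]
) -> ConditionalExpectation:
    """Eq.-style conditional expectation for an ordered pair of changes.

    ``snp_counts`` maps ChangeKeys (all three frames of each SNP) to counts.
    """
    if change2.triplet != change1.derived_triplet:
        raise ValueError("change2 must act on the triplet created by change1")
    if change2.pos == change1.pos:
        raise ValueError("change2 must hit a different position than change1")
    total = sum(snp_counts.values())
    p1 = snp_counts.get(change1, 0) / total if total else 0.0
    inter = change1.derived_triplet
    denom = 0.0
    for pos in (1, 2, 3):
        if pos == change1.pos:
            continue
        for d in BASES:
            if d == inter[pos - 1]:
                continue
            denom += snp_counts.get(ChangeKey(inter, pos, d), 0)
    path = TripletPath(change1.triplet, change1.pos, change1.derived,
                       change2.pos, change2.derived)
    if denom == 0:
        return ConditionalExpectation(path, p1, float("nan"), float("nan"), False)
    p2 = snp_counts.get(change2, 0) / denom
    return ConditionalExpectation(path, p1, p2, p1 * p2, True)


@dataclass
class ObservedExpectedRecord:
    path: TripletPath
    observed: float
    expected: float
    first_base_change: str  # e.g. "A>G"
    cpg_change: str  # "creates_cpg>destroys_cpg" etc. (step1 effect > step2)
    region: str = "intergenic"
    defined: bool = True


def _path_cpg_label(path: TripletPath) -> str:
    # flanks outside the triplet are unknown for a path class; evaluate CpG
    # effects within the triplet by padding with a non-C/non-G base
    e1 = cpg_effect(path.step1, "A", "A").value
    e2 = cpg_effect(path.step2, "A", "A").value
    return f"{e1}>{e2}"


def expected_sdm_counts(
    snp_counts: dict[ChangeKey, float],
    observed_counts: dict[TripletPath, float],
    region: str = "intergenic",
    mode: str = "proportion",
    triplet_abundance: dict[str, int] | None = None,
) -> list[ObservedExpectedRecord]:
    """Observed vs expected counts over all valid path classes.

    Expectations are normalized over defined classes and scaled so that the
    expected total equals the observed total.  Classes with an undefined
    conditional (zero denominator) are flagged and excluded from the scale.

    ``mode="proportion"`` (default) uses the proportion-based conditional:
    the second change's SNP count over all SNP counts at the intermediate
    triplet's other positions.  ``mode="rate"`` is the abundance-weighted
    variant: the second change's SNP count divided by the genomic abundance
    of the intermediate triplet (a per-site rate), which models a second
    mutation whose hazard is proportional to the absolute mutability of the
    created context; it requires ``triplet_abundance``.
    """
    if mode not in ("proportion", "rate"):
        raise ValueError(f"unknown conditional mode {mode!r}")
    if mode == "rate" and triplet_abundance is None:
        raise ValueError("rate mode requires triplet_abundance")
    total_snp = sum(snp_counts.values())
    paths = enumerate_path_classes()
    probs = {}
    undefined = []
    for path in paths:
        if mode == "proportion":
            ce = conditional_probability(path.step1, path.step2, snp_counts)
            if ce.defined:
                probs[path] = ce.p_joint
            else:
                undefined.append(path)
        else:
            ab = triplet_abundance.get(path.intermediate, 0)
            if ab == 0 or total_snp == 0:
                undefined.append(path)
                continue
            p1 = snp_counts.get(path.step1, 0) / total_snp
            probs[path] = p1 * snp_counts.get(path.step2, 0) / ab
    total_obs = sum(observed_counts.get(p, 0) for p in probs)
    total_p = sum(probs.values())
    records = []
    for path in paths:
        obs = observed_counts.get(path, 0)
        if path in probs:
            exp = total_obs * probs[path] / total_p if total_p else 0.0
            defined = True
        else:
            exp = float("nan")
            defined = False
        records.append(
            ObservedExpectedRecord(
                path=path,
                observed=obs,
                expected=exp,
                first_base_change=path.step1.substitution,
                cpg_change=_path_cpg_label(path),
                region=region,
                defined=defined,
            )
        )
    if undefined:
        log.info("%d path classes had undefined expectations", len(undefined))
    return records


def records_to_frame(records: list[ObservedExpectedRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "path": [r.path.label for r in records],
            "observed": [r.observed for r in records],
            "expected": [r.expected for r in records],
            "first_base_change": [r.first_base_change for r in records],
            "cpg_change": [r.cpg_change for r in records],
            "region": [r.region for r in records],
            "defined": [r.defined for r in records],
        }
    )


@dataclass
class TripletAbundance:
    """Triplet counts in intergenic regions and codon counts in CDS."""

    intergenic: dict[str, int]
    coding: dict[str, int]

    def ratio(self, triplet: str) -> float:
        c = self.coding.get(triplet, 0)
        if c == 0:
            raise KeyError(f"no coding abundance for triplet {triplet}")
        return self.intergenic.get(triplet, 0) / c


def count_triplet_abundance(
    ref_by_chrom: dict[str, str], gene_models, buffer: int = 2
) -> TripletAbundance:
    """Count reference-strand triplets outside genes and codons inside CDS.

    Intergenic triplets are counted in a sliding window over every position
    at least ``buffer`` bases away from any CDS interval; coding triplets are
    the codons of each transcript on its coding strand.
    """
    intergenic: dict[str, int] = {}
    coding: dict[str, int] = {}
    for chrom, seq in ref_by_chrom.items():
        seq = seq.upper()
        excluded = np.zeros(len(seq), dtype=bool)
        for start, end in gene_models.coding_intervals(chrom):
            lo = max(0, start - buffer)
            hi = min(len(seq), end + buffer)
            excluded[lo:hi] = True
        for i in range(len(seq) - 2):
            if excluded[i] or excluded[i + 1] or excluded[i + 2]:
                continue
            trip = seq[i : i + 3]
            if all(b in "ACGT" for b in trip):
                intergenic[trip] = intergenic.get(trip, 0) + 1
    for tid, info in gene_models.transcripts.items():
        chrom = info["chrom"]
        seq = ref_by_chrom[chrom].upper()
        # walk codons via the lookup structure
        n = info["n_codons"]
        # rebuild codon positions from intervals
        positions: list[int] = []
        for start, end in info["intervals"]:
            positions.extend(range(start, end))
        if info["strand"] == "-":
            positions.reverse()
        positions = positions[: 3 * n]
        from Bio.Seq import Seq as _Seq

        for i in range(0, len(positions), 3):
            codon = "".join(seq[p] for p in positions[i : i + 3])
            if info["strand"] == "-":
                codon = str(_Seq(codon).complement())
            coding[codon] = coding.get(codon, 0) + 1
    return TripletAbundance(intergenic=intergenic, coding=coding)


def expected_coding_counts(
    intergenic_sdm_counts: dict, abundance: TripletAbundance, total_coding_sdms: float
) -> pd.DataFrame:
    """Expected coding SDM counts from intergenic counts.

    Each intergenic count is divided by the intergenic/coding abundance ratio
    of its ancestral triplet, the adjusted values are renormalized to
    fractions, and scaled by the total number of coding SDMs.  Keys may be
    TripletPath or plain labels as long as the ancestral triplet is
    recoverable via ``key.ancestral`` or ``key[:3]``.
    """
    rows = []
    adjusted = {}
    for key, count in intergenic_sdm_counts.items():
        anc = key.ancestral if hasattr(key, "ancestral") else str(key)[:3]
        try:
            r = abundance.ratio(anc)
        except KeyError:
            log.warning("path %s: missing triplet abundance; excluded", key)
            continue
        adjusted[key] = count / r
    total_adj = sum(adjusted.values())
    for key, adj in adjusted.items():
        frac = adj / total_adj if total_adj else 0.0
        rows.append(
            {
                "path": key.label if hasattr(key, "label") else str(key),
                "intergenic_count": intergenic_sdm_counts[key],
                "adjusted": adj,
                "fraction": frac,
                "expected_coding": frac * total_coding_sdms,
            }
        )
    return pd.DataFrame(rows)
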