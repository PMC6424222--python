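"""Classification of neighbouring polarized variant pairs.

A pair of adjacent polymorphisms is summarised by which combinations of
ancestral (A) and derived (D) alleles are observed across all haplotypes in
the cohort:

* ``DD`` absent                     -> unlinked (two independent SNPs)
* ``DD`` only (besides ``AA``)      -> putative MNP (single mutational event)
* ``DD`` plus exactly one of
  ``DA``/``AD``                     -> SDM; the site that is derived in the
                                       observed intermediate mutated first
* ``DD`` plus both intermediates    -> ambiguous (recombination or recurrent
                                       mutation); excluded

Classification is decided on the union of all cohort haplotypes ("observed in
any population"); per-population analyses subset carriers afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PolarizedVariant, PopulationPanel


@dataclass(frozen=True)
class PairClassification:
    label: str  # SDM | MNP_candidate | ambiguous_both_intermediates | unlinked
    reason: str = ""


@dataclass
class AdjacentPair:
    left: PolarizedVariant
    right: PolarizedVariant

    def __post_init__(self) -> None:
        if self.left.chrom != self.right.chrom:
            raise ValueError("pair spans chromosomes")
        if self.right.pos - self.left.pos != 1:
            raise ValueError(
                f"pair positions {self.left.pos},{self.right.pos} not adjacent"
            )

    def combinations(self) -> dict[str, int]:
        """Counts of the observed (left, right) A/D combinations."""
        l = self.left.derived_mask
        r = self.right.derived_mask
        return {
            "AA": int(np.sum(~l & ~r)),
            "DA": int(np.sum(l & ~r)),
            "AD": int(np.sum(~l & r)),
            "DD": int(np.sum(l & r)),
        }


@dataclass
class SDMCall:
    chrom: str
    pos: int  # left position, 0-based
    anc_dinuc: str
    der_dinuc: str
    order: str  # left_first | right_first
    left: PolarizedVariant
    right: PolarizedVariant
    chain: int = 2
    intermediate_groups: tuple[str, ...] = ()

    @property
    def dd_mask(self) -> np.ndarray:
        return self.left.derived_mask & self.right.derived_mask


def classify_pair(pair: AdjacentPair) -> PairClassification:
    combos = pair.combinations()
    dd, da, ad = combos["DD"], combos["DA"], combos["AD"]
    if dd == 0:
        return PairClassification("unlinked", "no double-derived haplotype")
    if da == 0 and ad == 0:
        reason = "no intermediate haplotype observed"
        if dd == 1:
            reason += "; singleton_dd"
        return PairClassification("MNP_candidate", reason)
    if da > 0 and ad > 0:
        return PairClassification(
            "ambiguous_both_intermediates", "both single-derived combinations observed"
        )
    order = "left_first" if da > 0 else "right_first"
    return PairClassification("SDM", order)


def run_length_filter(positions: list[int]) -> dict[int, int]:
    """Chain length (run of consecutive variant positions) per position."""
    chain: dict[int, int] = {}
    if not positions:
        return chain
    positions = sorted(positions)
    start = 0
    for i in range(1, len(positions) + 1):
        if i == len(positions) or positions[i] != positions[i - 1] + 1:
            run = positions[start:i]
            for p in run:
                chain[p] = len(run)
            start = i
    return chain


@dataclass
class CallSet:
    """Result of scanning a polarized variant list for adjacent pairs."""

    calls: list[SDMCall]
    classifications: pd.DataFrame  # chrom, pos, label, reason, chain
    counts: dict[str, int]


def call_sdms(
    variants: list[PolarizedVariant], panel: PopulationPanel | None = None
) -> CallSet:
    """Evaluate every adjacent pair of polarized variants.

    Variants must be position-sorted.  Chains of >= 3 consecutive variants are
    kept but annotated with their run length.
    """
    calls: list[SDMCall] = []
    rows = []
    counts = {
        "SDM": 0,
        "MNP_candidate": 0,
        "ambiguous_both_intermediates": 0,
        "unlinked": 0,
    }
    by_chrom: dict[str, list[PolarizedVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, vs in by_chrom.items():
        vs = sorted(vs, key=lambda v: v.pos)
        chain = run_length_filter([v.pos for v in vs])
        for a, b in zip(vs, vs[1:]):
            if b.pos - a.pos != 1:
                continue
            pair = AdjacentPair(a, b)
            cls = classify_pair(pair)
            counts[cls.label] += 1
            run = max(chain[a.pos], chain[b.pos])
            rows.append(
                {
                    "chrom": chrom,
                    "pos": a.pos,
                    "label": cls.label,
                    "reason": cls.reason,
                    "chain": run,
                }
            )
            if cls.label == "SDM":
                order = cls.reason
                groups: tuple[str, ...] = ()
                if panel is not None:
                    inter_mask = (
                        (a.derived_mask & ~b.derived_mask)
                        if order == "left_first"
                        else (~a.derived_mask & b.derived_mask)
                    )
                    hap_groups = np.repeat(
                        panel.group_of_samples(a.sample_ids), 2
                    )
                    groups = tuple(sorted(set(hap_groups[inter_mask])))
                calls.append(
                    SDMCall(
                        chrom=chrom,
                        pos=a.pos,
                        anc_dinuc=a.anc_allele + b.anc_allele,
                        der_dinuc=a.der_allele + b.der_allele,
                        order=order,
                        left=a,
                        right=b,
                        chain=run,
                        intermediate_groups=groups,
                    )
                )
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "label", "reason", "chain"])
    return CallSet(calls=calls, classifications=frame, counts=counts)


def count_carriers(call: SDMCall, panel: PopulationPanel) -> dict[str, dict[str, int]]:
    """Carriers of an SDM per subpopulation and continental group.

    An individual is a carrier only if at least one of their haplotypes
    carries both derived alleles.
    """
    dd = call.dd_mask
    n = len(call.left.sample_ids)
    carrier = dd[0 : 2 * n : 2] | dd[1 : 2 * n : 2]
    subpops: dict[str, int] = {}
    groups: dict[str, int] = {}
    for i, sample in enumerate(call.left.sample_ids):
        if carrier[i]:
            subpops[panel.subpop(sample)] = subpops.get(panel.subpop(sample), 0) + 1
            groups[panel.group(sample)] = groups.get(panel.group(sample), 0) + 1
    return {"subpop": subpops, "group": groups}


def carrier_mask(call: SDMCall) -> np.ndarray:
    """Boolean per-individual carrier vector for one SDM."""
    dd = call.dd_mask
    n = len(call.left.sample_ids)
    return dd[0 : 2 * n : 2] | dd[1 : 2 * n : 2]


def calls_to_frame(callset: CallSet, panel: PopulationPanel | None = None) -> pd.DataFrame:
    """Tabular SDM call export (one row per SDM)."""
    rows = []
    for c in callset.calls:
        row = {
            "chrom": c.chrom,
            "pos1": c.pos + 1,
            "pos2": c.pos + 2,
            "anc_dinuc": c.anc_dinuc,
            "der_dinuc": c.der_dinuc,
            "order": c.order,
            "chain": c.chain,
        }
        if panel is not None:
            carriers = count_carriers(c, panel)
            for g in panel.groups:
                row[f"carriers_{g}"] = carriers["group"].get(g, 0)
        rows.append(row)
    return pd.DataFrame(rows)
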