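"""Triplet context, CpG effect and codon consequence annotation.

All change classes are keyed by a :class:`ChangeKey`: the ancestral triplet
(reference strand for noncoding changes, coding strand for codon changes),
which of the three triplet positions is mutated, and the derived base.  There
are 576 such keys (64 triplets x 3 positions x 3 alternative bases) — the same
universe used for single-base codon changes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Sequence

from Bio.Seq import Seq

from .io import AncestralSequence, GeneModelSet

log = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")
STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(codon: str) -> str:
    """Single-letter amino acid ('*' for stop)."""
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return str(Seq(codon).translate())


class ChangeKey(NamedTuple):
    """A single base change in triplet context.

    ``pos`` is 1-based within the triplet (the field convention used for
    spectrum labels such as "2 -> G").
    """

    triplet: str
    pos: int
    derived: str

    @property
    def ancestral_base(self) -> str:
        return self.triplet[self.pos - 1]

    @property
    def derived_triplet(self) -> str:
        i = self.pos - 1
        return self.triplet[:i] + self.derived + self.triplet[i + 1:]

    @property
    def substitution(self) -> str:
        """The base change irrespective of context, e.g. 'A>G'."""
        return f"{self.ancestral_base}>{self.derived}"

    def reverse_complement(self) -> "ChangeKey":
        return ChangeKey(
            revcomp(self.triplet), 4 - self.pos, self.derived.translate(COMPLEMENT)
        )

    def label(self) -> str:
        return f"{self.triplet}:{self.pos}>{self.derived}"


def make_change(triplet: str, pos: int, derived: str) -> ChangeKey:
    key = ChangeKey(triplet, pos, derived)
    if key.ancestral_base == derived:
        raise ValueError(f"{triplet} position {pos}: derived base equals ancestral")
    if any(b not in BASES for b in triplet) or derived not in BASES:
        raise ValueError("triplet and derived base must be A/C/G/T")
    return key


def all_change_keys() -> list[ChangeKey]:
    """The full universe of 576 valid change keys."""
    out = []
    for trip in ("".join(p) for p in itertools.product(BASES, repeat=3)):
        for pos in (1, 2, 3):
            for d in BASES:
                if d != trip[pos - 1]:
                    out.append(ChangeKey(trip, pos, d))
    return out


CODON_CHANGE_INDEX = {k: i for i, k in enumerate(all_change_keys())}


class CpGEffect(str, Enum):
    CREATES = "creates_cpg"
    DESTROYS = "destroys_cpg"
    BOTH = "both"
    NONE = "none"


def cpg_effect(change: ChangeKey, flank5: str, flank3: str) -> CpGEffect:
    """Net effect of a single base change on CpG dinucleotides.

    Evaluated on the 5-mer ``flank5 + triplet + flank3`` so that CpGs formed
    with either immediate neighbour of the triplet are seen.
    """
    before = flank5 + change.triplet + flank3
    after = flank5 + change.derived_triplet + flank3
    sites_before = {i for i in range(4) if before[i : i + 2] == "CG"}
    sites_after = {i for i in range(4) if after[i : i + 2] == "CG"}
    created = sites_after - sites_before
    destroyed = sites_before - sites_after
    if created and destroyed:
        return CpGEffect.BOTH
    if created:
        return CpGEffect.CREATES
    if destroyed:
        return CpGEffect.DESTROYS
    return CpGEffect.NONE


def consequence(anc_codon: str, der_codon: str) -> str:
    """Consequence class of a 1- or 2-base codon change.

    stop_gained when the derived codon is a stop and the ancestral is not,
    stop_lost conversely, synonymous when the encoded amino acids are equal,
    otherwise missense.
    """
    aa_anc = translate(anc_codon)
    aa_der = translate(der_codon)
    if aa_der == "*" and aa_anc != "*":
        return "stop_gained"
    if aa_anc == "*" and aa_der != "*":
        return "stop_lost"
    if aa_anc == aa_der:
        return "synonymous"
    return "missense"


@dataclass(frozen=True)
class CodonChangeRecord:
    """One of the 576 single-base codon changes."""

    key: ChangeKey
    consequence: str
    cpg_effect: CpGEffect
    index: int

    @classmethod
    def from_key(
        cls, key: ChangeKey, flank5: str = "N", flank3: str = "N"
    ) -> "CodonChangeRecord":
        f5 = flank5 if flank5 in BASES else "A"
        f3 = flank3 if flank3 in BASES else "A"
        return cls(
            key=key,
            consequence=consequence(key.triplet, key.derived_triplet),
            cpg_effect=cpg_effect(key, f5, f3),
            index=CODON_CHANGE_INDEX[key],
        )


# ---------------------------------------------------------------------------
# noncoding SNP triplet records
# ---------------------------------------------------------------------------


def triplet_records_for_snp(
    pos: int, anc_base: str, der_base: str, seq_lookup
) -> list[ChangeKey]:
    """Record a noncoding SNP in all three frames containing it.

    ``seq_lookup(pos) -> base or None`` supplies the (ancestral) flanking
    bases; frames that would extend past the contig end are skipped with a
    warning.  All records are on the reference strand.
    """
    records = []
    for frame_pos in (1, 2, 3):
        start = pos - (frame_pos - 1)
        bases = []
        ok = True
        for i in range(3):
            b = anc_base if start + i == pos else seq_lookup(start + i)
            if b is None or b not in BASES:
                ok = False
                break
            bases.append(b)
        if not ok:
            log.warning("SNP at %d: frame %d unavailable near contig end", pos, frame_pos)
            continue
        records.append(ChangeKey("".join(bases), frame_pos, der_base))
    return records


# ---------------------------------------------------------------------------
# SDM paths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SDMPath:
    """An ancestral -> intermediate -> derived trajectory for one SDM.

    Noncoding SDMs yield two paths (one anchored on the 5' neighbour, one on
    the 3'); within-codon coding SDMs yield one path on the coding strand.
    """

    kind: str  # "noncoding" | "coding"
    anchor: str  # "5p" | "3p" | "codon"
    ancestral: str
    intermediate: str
    derived: str
    step1: ChangeKey
    step2: ChangeKey
    chrom: str
    pos: int  # left position of the dinucleotide, 0-based
    step1_consequence: str | None = None
    step2_consequence: str | None = None
    net_consequence: str | None = None
    transcript: str | None = None
    strand: str | None = None

    @property
    def path_label(self) -> str:
        return f"{self.ancestral}>{self.intermediate}>{self.derived}"

    def reverse_complement(self) -> "SDMPath":
        return SDMPath(
            kind=self.kind,
            anchor={"5p": "3p", "3p": "5p"}.get(self.anchor, self.anchor),
            ancestral=revcomp(self.ancestral),
            intermediate=revcomp(self.intermediate),
            derived=revcomp(self.derived),
            step1=self.step1.reverse_complement(),
            step2=self.step2.reverse_complement(),
            chrom=self.chrom,
            pos=self.pos,
            step1_consequence=self.step1_consequence,
            step2_consequence=self.step2_consequence,
            net_consequence=self.net_consequence,
            transcript=self.transcript,
            strand=self.strand,
        )


def _apply(triplet: str, pos: int, base: str) -> str:
    return triplet[: pos - 1] + base + triplet[pos:]


def sdm_path_records(call, anc_seq: AncestralSequence, gene_models: GeneModelSet | None
                     ) -> tuple[list[SDMPath], list[str]]:
    """Build path records for one SDM call.

    Returns ``(paths, flags)``.  Noncoding calls yield a 5'-anchored and a
    3'-anchored triplet path on the reference strand; calls falling inside a
    codon yield one path per covering transcript frame, on the coding strand,
    with per-step and net consequences.  Calls whose two bases span a codon
    boundary are flagged ``cross_codon`` and produce no codon path.
    """
    p = call.pos
    chrom = call.chrom
    flags: list[str] = []
    paths: list[SDMPath] = []
    first_left = call.order == "left_first"
    anc_l, anc_r = call.anc_dinuc
    der_l, der_r = call.der_dinuc

    coding_ctx = []
    if gene_models is not None:
        ctx_l = gene_models.codon_contexts(chrom, p)
        ctx_r = gene_models.codon_contexts(chrom, p + 1)
        if ctx_l or ctx_r:
            by_t_l = {c.transcript: c for c in ctx_l}
            by_t_r = {c.transcript: c for c in ctx_r}
            shared = set(by_t_l) & set(by_t_r)
            same_codon = [
                (by_t_l[t], by_t_r[t])
                for t in shared
                if by_t_l[t].codon_index == by_t_r[t].codon_index
            ]
            if same_codon:
                coding_ctx = same_codon
            else:
                flags.append("cross_codon")
                return paths, flags

    if coding_ctx:
        seen = set()
        for cl, cr in coding_ctx:
            def anc_base_at(q, _p=p):
                if q == _p:
                    return anc_l
                if q == _p + 1:
                    return anc_r
                b = anc_seq.base(q)
                if anc_seq.confidence(q) != "high":
                    return None
                return b

            bases = [anc_base_at(q) for q in cl.codon_positions]
            if any(b is None for b in bases):
                flags.append("low_confidence_flank")
                continue
            codon = "".join(bases)
            strand = cl.strand
            if strand == "-":
                codon = codon.translate(COMPLEMENT)
            off_l = cl.codon_positions.index(p)  # offset of left base, coding order
            off_r = cl.codon_positions.index(p + 1)
            d_l, d_r = der_l, der_r
            if strand == "-":
                d_l, d_r = d_l.translate(COMPLEMENT), d_r.translate(COMPLEMENT)
            if first_left:
                off1, off2, d1, d2 = off_l, off_r, d_l, d_r
            else:
                off1, off2, d1, d2 = off_r, off_l, d_r, d_l
            inter = _apply(codon, off1 + 1, d1)
            der = _apply(inter, off2 + 1, d2)
            key = (codon, inter, der)
            if key in seen:
                continue
            seen.add(key)
            paths.append(
                SDMPath(
                    kind="coding",
                    anchor="codon",
                    ancestral=codon,
                    intermediate=inter,
                    derived=der,
                    step1=ChangeKey(codon, off1 + 1, d1),
                    step2=ChangeKey(inter, off2 + 1, d2),
                    chrom=chrom,
                    pos=p,
                    step1_consequence=consequence(codon, inter),
                    step2_consequence=consequence(inter, der),
                    net_consequence=consequence(codon, der),
                    transcript=cl.transcript,
                    strand=strand,
                )
            )
        if len(coding_ctx) > 1:
            flags.append("multi_transcript")
        return paths, flags

    # noncoding: two anchored triplet paths on the reference strand
    for anchor in ("5p", "3p"):
        if anchor == "5p":
            fpos = p - 1
        else:
            fpos = p + 2
        if not 0 <= fpos < len(anc_seq):
            flags.append(f"contig_edge_{anchor}")
            continue
        if anc_seq.confidence(fpos) != "high":
            flags.append("low_confidence_flank")
            continue
        flank = anc_seq.base(fpos)
        if flank not in BASES:
            flags.append("low_confidence_flank")
            continue
        if anchor == "5p":
            trip = flank + anc_l + anc_r
            pos_l, pos_r = 2, 3
        else:
            trip = anc_l + anc_r + flank
            pos_l, pos_r = 1, 2
        if first_left:
            pos1, pos2, d1, d2 = pos_l, pos_r, der_l, der_r
        else:
            pos1, pos2, d1, d2 = pos_r, pos_l, der_r, der_l
        inter = _apply(trip, pos1, d1)
        der = _apply(inter, pos2, d2)
        paths.append(
            SDMPath(
                kind="noncoding",
                anchor=anchor,
                ancestral=trip,
                intermediate=inter,
                derived=der,
                step1=ChangeKey(trip, pos1, d1),
                step2=ChangeKey(inter, pos2, d2),
                chrom=chrom,
                pos=p,
            )
        )
    return paths, flags
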