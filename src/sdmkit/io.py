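"""Readers and validators for the pipeline's external inputs.

External formats use their native 1-based coordinates (VCF, GFF3); every
in-memory position in this package is 0-based.  The conversion happens here,
at the boundary, and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhasedVariant:
    """A biallelic SNV with fully phased haplotype alleles.

    ``pos`` is 0-based.  ``haplotype_alleles`` is an int8 vector over the 2N
    haplotypes (sample order x [hapA, hapB]); 0 = ref allele, 1 = alt.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    haplotype_alleles: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError("alleles must be single A/C/G/T bases")
        if len(self.haplotype_alleles) != 2 * len(self.sample_ids):
            raise ValueError("haplotype vector length must be 2 x sample count")


@dataclass(frozen=True)
class PolarizedVariant:
    """A variant with ancestral/derived alleles resolved.

    ``derived_mask`` marks haplotypes carrying the derived allele.
    """

    chrom: str
    pos: int
    anc_allele: str
    der_allele: str
    derived_mask: np.ndarray
    sample_ids: tuple[str, ...]


@dataclass(frozen=True)
class Rejection:
    """A variant excluded during polarization, with the reason."""

    variant: PhasedVariant
    reason: str  # "low_confidence" | "mismatch"


@dataclass
class AncestralSequence:
    """Per-chromosome ancestral base string with case-encoded confidence.

    Uppercase = high confidence, lowercase = low confidence, '.', '-' or 'N'
    = unknown (the encoding used by the 1000 Genomes ancestral alignments).
    """

    chrom: str
    raw: str

    def __len__(self) -> int:
        return len(self.raw)

    def base(self, pos: int) -> str:
        if not 0 <= pos < len(self.raw):
            raise IndexError(f"position {pos} outside ancestral sequence")
        return self.raw[pos].upper()

    def confidence(self, pos: int) -> str:
        """Return 'high', 'low' or 'unknown' for a 0-based position."""
        c = self.raw[pos]
        if c in ".-" or c.upper() == "N":
            return "unknown"
        return "high" if c.isupper() else "low"


@dataclass
class PopulationPanel:
    """Sample -> (subpopulation, continental group) mapping."""

    table: pd.DataFrame  # index: sample; columns: pop, super_pop

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.table["super_pop"].unique()))

    @property
    def subpopulations(self) -> tuple[str, ...]:
        return tuple(sorted(self.table["pop"].unique()))

    def subpop(self, sample: str) -> str:
        return self.table.at[sample, "pop"]

    def group(self, sample: str) -> str:
        return self.table.at[sample, "super_pop"]

    def group_of_samples(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from panel: {missing[:5]}")
        return self.table.loc[list(sample_ids), "super_pop"].to_numpy()


@dataclass(frozen=True)
class CodonContext:
    """Where a genomic position sits inside a transcript's reading frame."""

    transcript: str
    strand: str
    codon_index: int
    offset: int  # 0-2, position within codon on the coding strand
    codon_positions: tuple[int, int, int]  # genomic 0-based, coding order


class GeneModelSet:
    """CDS intervals plus a genomic-position -> codon lookup.

    Transcripts whose phase-adjusted CDS length is not divisible by 3 are
    dropped with a warning.
    """

    def __init__(self) -> None:
        self._lookup: dict[tuple[str, int], list[CodonContext]] = {}
        self.transcripts: dict[str, dict] = {}

    def add_transcript(
        self,
        transcript: str,
        chrom: str,
        strand: str,
        cds_intervals: Sequence[tuple[int, int]],  # 0-based half-open
        phase: int = 0,
    ) -> bool:
        if strand not in "+-":
            raise ValueError(f"transcript {transcript}: missing/invalid strand")
        ivals = sorted(cds_intervals)
        positions: list[int] = []
        for start, end in ivals:
            positions.extend(range(start, end))
        if strand == "-":
            positions.reverse()
        positions = positions[phase:]
        if len(positions) % 3 != 0:
            log.warning(
                "transcript %s: CDS length %d not divisible by 3; dropped",
                transcript,
                len(positions),
            )
            return False
        self.transcripts[transcript] = {
            "chrom": chrom,
            "strand": strand,
            "intervals": ivals,
            "n_codons": len(positions) // 3,
        }
        for i in range(0, len(positions), 3):
            codon = tuple(positions[i : i + 3])
            for off, p in enumerate(codon):
                self._lookup.setdefault((chrom, p), []).append(
                    CodonContext(transcript, strand, i // 3, off, codon)
                )
        return True

    def codon_contexts(self, chrom: str, pos: int) -> list[CodonContext]:
        """All transcript frames covering a position ([] if noncoding)."""
        return self._lookup.get((chrom, pos), [])

    def is_coding(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._lookup

    def coding_intervals(self, chrom: str) -> list[tuple[int, int]]:
        out = []
        for t in self.transcripts.values():
            if t["chrom"] == chrom:
                out.extend(t["intervals"])
        return sorted(out)

    def codon_seq(self, ctx: CodonContext, seq_lookup) -> str:
        """Codon string on the coding strand; ``seq_lookup(pos) -> base``."""
        bases = [seq_lookup(p) for p in ctx.codon_positions]
        codon = "".join(bases)
        if ctx.strand == "-":
            codon = str(Seq(codon).complement())
        return codon


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_phased_variants(
    vcf_source: str, region: str | None = None
) -> tuple[list[PhasedVariant], int]:
    """Read biallelic, fully phased SNVs from a VCF.

    Returns the variants in position order plus a counter of skipped records
    (multiallelic or indel).  An unphased genotype is a hard error naming the
    offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_source)
    samples = tuple(vcf.samples)
    out: list[PhasedVariant] = []
    skipped = 0
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        if rec.REF not in BASES or rec.ALT[0] not in BASES:
            skipped += 1
            continue
        gts = rec.genotypes  # [[a, b, phased], ...]
        alleles = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            if len(gt) < 3 or not gt[2]:
                raise ValueError(
                    f"unphased genotype at {rec.CHROM}:{rec.POS} "
                    f"(sample {samples[i]})"
                )
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {rec.CHROM}:{rec.POS}")
            alleles[2 * i] = a
            alleles[2 * i + 1] = b
        out.append(
            PhasedVariant(
                chrom=rec.CHROM,
                pos=rec.POS - 1,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                haplotype_alleles=alleles,
                sample_ids=samples,
            )
        )
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out, skipped


def write_phased_variants(
    variants: Sequence[PhasedVariant],
    path: str,
    contig_lengths: dict[str, int],
    sample_ids: Sequence[str] | None = None,
) -> None:
    """Write variants as a minimal phased VCF 4.2 (text)."""
    if sample_ids is not None:
        samples = tuple(sample_ids)
    elif variants:
        samples = variants[0].sample_ids
    else:
        samples = ()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(samples)) + "\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            gts = [
                f"{v.haplotype_alleles[2 * i]}|{v.haplotype_alleles[2 * i + 1]}"
                for i in range(len(v.sample_ids))
            ]
            row = [v.chrom, str(v.pos + 1), ".", v.ref_allele, v.alt_allele,
                   ".", "PASS", ".", "GT"] + gts
            fh.write("\t".join(row) + "\n")


def polarize(
    variant: PhasedVariant, anc: AncestralSequence
) -> PolarizedVariant | Rejection:
    """Resolve ancestral/derived alleles from the ancestral sequence.

    The four outcomes (match ref, match alt, low confidence, mismatch)
    partition all inputs; the first two yield a PolarizedVariant.
    """
    if not 0 <= variant.pos < len(anc):
        raise IndexError(
            f"variant {variant.chrom}:{variant.pos + 1} outside ancestral sequence"
        )
    if anc.confidence(variant.pos) != "high":
        return Rejection(variant, "low_confidence")
    base = anc.base(variant.pos)
    if base == variant.ref_allele:
        anc_allele, der_allele = variant.ref_allele, variant.alt_allele
        mask = variant.haplotype_alleles == 1
    elif base == variant.alt_allele:
        anc_allele, der_allele = variant.alt_allele, variant.ref_allele
        mask = variant.haplotype_alleles == 0
    else:
        return Rejection(variant, "mismatch")
    return PolarizedVariant(
        chrom=variant.chrom,
        pos=variant.pos,
        anc_allele=anc_allele,
        der_allele=der_allele,
        derived_mask=np.asarray(mask, dtype=bool),
        sample_ids=variant.sample_ids,
    )


def polarize_all(
    variants: Sequence[PhasedVariant], anc_by_chrom: dict[str, AncestralSequence]
) -> tuple[list[PolarizedVariant], dict[str, int]]:
    """Polarize a variant list; returns kept variants and rejection counts."""
    kept: list[PolarizedVariant] = []
    rejected = {"low_confidence": 0, "mismatch": 0}
    for v in variants:
        res = polarize(v, anc_by_chrom[v.chrom])
        if isinstance(res, Rejection):
            rejected[res.reason] += 1
        else:
            kept.append(res)
    return kept, rejected


def read_fasta(path: str) -> dict[str, str]:
    """Chrom -> raw sequence string (case preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_ancestral(path: str) -> dict[str, AncestralSequence]:
    return {c: AncestralSequence(c, s) for c, s in read_fasta(path).items()}


def read_panel(panel_source: str) -> PopulationPanel:
    """Read a sample/pop/super_pop TSV into a PopulationPanel."""
    df = pd.read_csv(panel_source, sep="\t", dtype=str)
    required = {"sample", "pop", "super_pop"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicated sample ids in panel: {dups[:5]}")
    return PopulationPanel(df.set_index("sample")[["pop", "super_pop"]])


def read_gene_models(gff_source: str) -> GeneModelSet:
    """Build a GeneModelSet from the CDS features of a GFF3/GTF file."""
    import gffutils

    db = gffutils.create_db(
        gff_source,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_transcript: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        if cds.strand not in "+-":
            log.warning("CDS without strand at %s:%s; rejected", cds.seqid, cds.start)
            continue
        parents = cds.attributes.get("Parent") or cds.attributes.get("transcript_id")
        tid = parents[0] if parents else cds.id
        entry = by_transcript.setdefault(
            tid, {"chrom": cds.seqid, "strand": cds.strand, "ivals": [], "phases": []}
        )
        entry["ivals"].append((cds.start - 1, cds.end))  # GFF 1-based closed
        try:
            entry["phases"].append((cds.start - 1, int(cds.frame)))
        except (TypeError, ValueError):
            entry["phases"].append((cds.start - 1, 0))
    models = GeneModelSet()
    for tid, entry in by_transcript.items():
        ivals = sorted(entry["ivals"])
        phases = dict(entry["phases"])
        # phase of the first CDS in coding order
        first = ivals[0][0] if entry["strand"] == "+" else ivals[-1][0]
        models.add_transcript(
            tid, entry["chrom"], entry["strand"], ivals, phase=phases.get(first, 0)
        )
    return models
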