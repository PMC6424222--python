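import numpy as np
import pandas as pd
import pytest

from sdmkit.io import (
    AncestralSequence,
    GeneModelSet,
    PhasedVariant,
    PolarizedVariant,
    PopulationPanel,
)


def make_polarized(
    chrom: str,
    pos: int,
    anc: str,
    der: str,
    derived_mask,
    sample_ids=None,
) -> PolarizedVariant:
    mask = np.asarray(derived_mask, dtype=bool)
    if sample_ids is None:
        sample_ids = tuple(f"s{i}" for i in range(len(mask) // 2))
    return PolarizedVariant(
        chrom=chrom,
        pos=pos,
        anc_allele=anc,
        der_allele=der,
        derived_mask=mask,
        sample_ids=tuple(sample_ids),
    )


@pytest.fixture
def small_panel() -> PopulationPanel:
    samples = [f"s{i}" for i in range(4)]
    return PopulationPanel(
        pd.DataFrame(
            {"pop": ["GBR", "GBR", "YRI", "YRI"], "super_pop": ["EUR", "EUR", "AFR", "AFR"]},
            index=pd.Index(samples, name="sample"),
        )
    )


@pytest.fixture
def toy_anc() -> AncestralSequence:
    #            0123456789
    return AncestralSequence("1", "TACGTACGTA")


def write_vcf(path, records, samples=("s0", "s1")):
    """records: list of (chrom, pos1, ref, alt, [gt strings])"""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1,length=1000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path
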