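import itertools

import pytest

from sdmkit import contexts
from sdmkit.caller import SDMCall
from sdmkit.io import AncestralSequence, GeneModelSet

from conftest import make_polarized

BASES = "ACGT"


class TestChangeKey:
    def test_universe_size_is_576(self):
        assert len(contexts.all_change_keys()) == 576

    def test_reverse_complement_involution_exhaustive(self):
        for key in contexts.all_change_keys():
            assert key.reverse_complement().reverse_complement() == key

    def test_derived_triplet(self):
        key = contexts.ChangeKey("ACG", 2, "G")
        assert key.derived_triplet == "AGG"
        assert key.substitution == "C>G"

    def test_same_base_change_rejected(self):
        with pytest.raises(ValueError):
            contexts.make_change("ACG", 1, "A")


class TestTripletRecords:
    def test_three_frames_on_reference_strand(self):
        # extended context T-A[C]G-T around a C>T change
        seq = "TACGT"
        records = contexts.triplet_records_for_snp(
            2, "C", "T", lambda p: seq[p] if 0 <= p < 5 else None
        )
        assert set(records) == {
            contexts.ChangeKey("ACG", 2, "T"),
            contexts.ChangeKey("CGT", 1, "T"),
            contexts.ChangeKey("TAC", 3, "T"),
        }

    def test_contig_start_yields_two_records(self):
        seq = "ACGT"
        records = contexts.triplet_records_for_snp(
            1, "C", "T", lambda p: seq[p] if 0 <= p < 4 else None
        )
        assert len(records) == 2

    def test_reverse_strand_reading_not_collapsed(self):
        """A G>A change is recorded on the reference strand, never folded
        onto its C>T complement."""
        seq = "TACGT"
        records = contexts.triplet_records_for_snp(
            3, "G", "A", lambda p: seq[p] if 0 <= p < 5 else None
        )
        assert all(k.derived == "A" for k in records)
        assert contexts.ChangeKey("ACG", 3, "A") in records


class TestCpGEffect:
    @pytest.mark.parametrize(
        "triplet,pos,derived,flank5,flank3,expected",
        [
            ("CAG", 2, "G", "T", "T", contexts.CpGEffect.CREATES),
            ("CGG", 1, "T", "A", "T", contexts.CpGEffect.DESTROYS),
            ("AAA", 2, "T", "A", "A", contexts.CpGEffect.NONE),
        ],
    )
    def test_examples(self, triplet, pos, derived, flank5, flank3, expected):
        key = contexts.ChangeKey(triplet, pos, derived)
        assert contexts.cpg_effect(key, flank5, flank3) is expected

    def test_exhaustive_against_string_scan(self):
        """All 5-mer contexts x all changes agree with direct window scans."""
        for f5, f3 in itertools.product(BASES, repeat=2):
            for trip in ("".join(t) for t in itertools.product(BASES, repeat=3)):
                for pos in (1, 2, 3):
                    for d in BASES:
                        if d == trip[pos - 1]:
                            continue
                        key = contexts.ChangeKey(trip, pos, d)
                        before = f5 + trip + f3
                        after = f5 + key.derived_triplet + f3
                        n_before = before.count("CG")
                        n_after = after.count("CG")
                        got = contexts.cpg_effect(key, f5, f3)
                        # independent census: compare CpG site sets
                        b = {i for i in range(4) if before[i:i+2] == "CG"}
                        a = {i for i in range(4) if after[i:i+2] == "CG"}
                        if a - b and b - a:
                            want = contexts.CpGEffect.BOTH
                        elif a - b:
                            want = contexts.CpGEffect.CREATES
                        elif b - a:
                            want = contexts.CpGEffect.DESTROYS
                        else:
                            want = contexts.CpGEffect.NONE
                        assert got is want, (key, f5, f3, n_before, n_after)


class TestConsequence:
    def test_exhaustive_single_base_against_codon_table(self):
        from Bio.Data.CodonTable import standard_dna_table

        fwd = standard_dna_table.forward_table
        stops = set(standard_dna_table.stop_codons)

        def aa(codon):
            return "*" if codon in stops else fwd[codon]

        for key in contexts.all_change_keys():
            anc, der = key.triplet, key.derived_triplet
            got = contexts.consequence(anc, der)
            if aa(der) == "*" and aa(anc) != "*":
                assert got == "stop_gained"
            elif aa(anc) == "*" and aa(der) != "*":
                assert got == "stop_lost"
            elif aa(anc) == aa(der):
                assert got == "synonymous"
            else:
                assert got == "missense"

    @pytest.mark.parametrize(
        "anc,der,expected",
        [
            ("CAG", "TGG", "missense"),  # Gln -> Trp, double change
            ("TGG", "TAG", "stop_gained"),  # Trp -> stop
            ("AAA", "AAA", "synonymous"),
            ("TGA", "TGG", "stop_lost"),
        ],
    )
    def test_examples(self, anc, der, expected):
        assert contexts.consequence(anc, der) == expected

    def test_invalid_codon_is_hard_error(self):
        with pytest.raises(ValueError):
            contexts.consequence("AXA", "AAA")


def _call(chrom, pos, anc_dinuc, der_dinuc, order, n_hap=4):
    left = make_polarized(chrom, pos, anc_dinuc[0], der_dinuc[0], [0] * n_hap)
    right = make_polarized(chrom, pos + 1, anc_dinuc[1], der_dinuc[1], [0] * n_hap)
    return SDMCall(chrom, pos, anc_dinuc, der_dinuc, order, left, right)


class TestSDMPaths:
    def test_noncoding_two_anchored_records(self):
        #        0123456
        anc = AncestralSequence("1", "GCCAGTT")
        # ancestral dinucleotide CA at (2,3), derived TG, A>G first
        call = _call("1", 2, "CA", "TG", "right_first")
        paths, flags = contexts.sdm_path_records(call, anc, None)
        assert flags == []
        assert len(paths) == 2
        by_anchor = {p.anchor: p for p in paths}
        p5 = by_anchor["5p"]
        assert (p5.ancestral, p5.intermediate, p5.derived) == ("CCA", "CCG", "CTG")
        p3 = by_anchor["3p"]
        assert (p3.ancestral, p3.intermediate, p3.derived) == ("CAG", "CGG", "TGG")
        # the step keys record which triplet position changed at each step
        assert p3.step1 == contexts.ChangeKey("CAG", 2, "G")
        assert p3.step2 == contexts.ChangeKey("CGG", 1, "T")

    def test_coding_thr_to_met_path(self):
        # gene on + strand covering one codon ACA at positions 3..5
        anc = AncestralSequence("1", "GGGACAGGG")
        models = GeneModelSet()
        models.add_transcript("t1", "1", "+", [(3, 6)])
        # SDM at (4, 5): C>T second, A>G first (right_first)
        call = _call("1", 4, "CA", "TG", "right_first")
        paths, flags = contexts.sdm_path_records(call, anc, models)
        assert len(paths) == 1
        p = paths[0]
        assert (p.ancestral, p.intermediate, p.derived) == ("ACA", "ACG", "ATG")
        assert p.step1_consequence == "synonymous"  # Thr ACA -> Thr ACG
        assert p.step2_consequence == "missense"  # Thr ACG -> Met ATG
        assert p.net_consequence == "missense"

    def test_cross_codon_flagged_and_excluded(self):
        anc = AncestralSequence("1", "GGGACAACAGGG")
        models = GeneModelSet()
        models.add_transcript("t1", "1", "+", [(3, 9)])
        call = _call("1", 5, "AA", "GG", "left_first")  # spans codons 0 and 1
        paths, flags = contexts.sdm_path_records(call, anc, models)
        assert paths == []
        assert "cross_codon" in flags

    def test_minus_strand_coding_path_is_on_coding_strand(self):
        # genomic codon TGT at 3..5 reads ACA on the - strand
        anc = AncestralSequence("1", "GGGTGTGGG")
        models = GeneModelSet()
        models.add_transcript("t1", "1", "-", [(3, 6)])
        # genomic dinucleotide GT at (4,5) -> CA; genome-left base first
        call = _call("1", 4, "GT", "CA", "left_first")
        paths, _ = contexts.sdm_path_records(call, anc, models)
        assert len(paths) == 1
        p = paths[0]
        assert p.strand == "-"
        assert (p.ancestral, p.intermediate, p.derived) == ("ACA", "AGA", "TGA")
        assert p.step1_consequence == "missense"  # Thr -> Arg
        assert p.net_consequence == "stop_gained"

    def test_record_count_invariant(self):
        anc = AncestralSequence("1", "GCCAGTTACGTT")
        calls = [
            _call("1", 2, "CA", "TG", "right_first"),
            _call("1", 7, "AC", "GT", "left_first"),
        ]
        total = 0
        for c in calls:
            ps, _ = contexts.sdm_path_records(c, anc, None)
            total += len(ps)
        assert total == 2 * len(calls)

    def test_path_reverse_complement_involution(self):
        anc = AncestralSequence("1", "GCCAGTT")
        call = _call("1", 2, "CA", "TG", "right_first")
        paths, _ = contexts.sdm_path_records(call, anc, None)
        for p in paths:
            assert p.reverse_complement().reverse_complement() == p
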