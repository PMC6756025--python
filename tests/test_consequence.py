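"""Consequence classification against brute-force oracles and the
synthetic worked example."""

import numpy as np
import pytest

from famlof.consequence import (
    ConsequenceCall,
    LofConfig,
    MultiallelicError,
    RefMismatchError,
    Variant,
    classify,
    extend_readthrough,
    is_putative_lof,
    model_exon_skip,
    predict_nmd,
)
from famlof.examples import synthetic_dis3_like
from famlof.reference import g_to_c

from conftest import make_gene, oracle_classify_cds_snv


def cds_genomic_positions(model):
    """All genomic positions inside the CDS, genomic order."""
    out = []
    for s, e in model.exons:
        lo, hi = max(s, model.cds_start_g), min(e, model.cds_end_g)
        out.extend(range(lo, hi + 1))
    return out


class TestClassifySnv:
    @pytest.mark.parametrize("fixture", ["toy_three_exon", "toy_three_exon_minus"])
    def test_exhaustive_cds_snvs_match_oracle(self, fixture, request):
        """Every CDS SNV of a <=300 nt toy gene classifies identically to
        the mutate-splice-translate oracle, on both strands."""
        genome, model = request.getfixturevalue(fixture)
        contig_seq = genome.contigs[model.contig]
        mismatches = []
        for gpos in cds_genomic_positions(model):
            ref = contig_seq[gpos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                call = classify(Variant(model.contig, gpos, ref, alt), model, genome)
                expected = oracle_classify_cds_snv(model, contig_seq, gpos, alt)
                if call.klass != expected:
                    mismatches.append((gpos, ref, alt, call.klass, expected))
        assert not mismatches

    def test_splice_donor_and_acceptor_classes(self, toy_three_exon):
        genome, model = toy_three_exon
        donor_pos = model.exons[0][1] + 1  # intron 1, +1 (a G by construction)
        call = classify(Variant("chrT", donor_pos, "G", "T"), model, genome)
        assert call.klass == "splice_donor"
        assert call.is_truncating
        acc_pos = model.exons[1][0] - 1  # intron 1, -1 (a G)
        call = classify(Variant("chrT", acc_pos, "G", "C"), model, genome)
        assert call.klass == "splice_acceptor"

    def test_deep_intronic_is_intronic(self, toy_three_exon):
        genome, model = toy_three_exon
        pos = model.exons[0][1] + 10
        ref = genome.base("chrT", pos)
        alt = "A" if ref != "A" else "C"
        call = classify(Variant("chrT", pos, ref, alt), model, genome)
        assert call.klass == "intronic"
        assert not call.is_truncating

    def test_ref_mismatch_raises(self, toy_three_exon):
        genome, model = toy_three_exon
        pos = model.cds_start_g  # an 'A' (ATG)
        with pytest.raises(RefMismatchError):
            classify(Variant("chrT", pos, "C", "G"), model, genome)

    def test_multiallelic_raises(self, toy_three_exon):
        genome, model = toy_three_exon
        with pytest.raises(MultiallelicError):
            classify(
                Variant("chrT", model.cds_start_g, "A", "C,G"), model, genome
            )

    def test_frameshift_indel(self, toy_three_exon):
        genome, model = toy_three_exon
        pos = model.cds_start_g + 3
        ref = genome.base("chrT", pos)
        call = classify(Variant("chrT", pos, ref, ref + "AT"), model, genome)
        assert call.klass == "frameshift"
        assert call.is_truncating


class TestExonSkip:
    def test_in_frame_skip_has_no_ptc(self, toy_three_exon):
        """The internal exon is 33 nt (multiple of 3): in-frame deletion
        of 11 residues, no frameshift, no premature stop."""
        genome, model = toy_three_exon
        skip = model_exon_skip(model, 1, genome)
        assert skip.resolved
        assert skip.frame_shifted is False
        assert skip.ptc_codon is None
        assert len(skip.mutant_protein) == 29 - 1 - 11  # 29 codons incl stop

    def test_terminal_exon_flagged_unresolved(self, toy_three_exon):
        genome, model = toy_three_exon
        for idx in (0, 2):
            skip = model_exon_skip(model, idx, genome)
            assert not skip.resolved
            assert "terminal" in skip.note

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_out_of_frame_skip_matches_oracle(self, strand):
        """10-nt internal exon: compare to a brute-force re-splice +
        translate of the exon-deleted CDS."""
        from conftest import oracle_translate

        ex1 = "ATGGCTGAAACCGGTGCTGAA"  # 21 nt
        ex2 = "TGTCATGATC"  # 10 nt -> frameshift
        ex3 = "GGTCATAAAGAGCTTCCCTCAGATTAA"  # 27 nt
        genome, model = make_gene([ex1, ex2, ex3], strand=strand)
        skip = model_exon_skip(model, 1, genome)
        assert skip.resolved and skip.frame_shifted
        expected_prot, _ = oracle_translate(ex1 + ex3)
        assert skip.mutant_protein == expected_prot
        assert skip.first_affected_codon == len(ex1) // 3 + 1

    def test_first_affected_codon_reported_even_if_residue_preserved(self):
        ex = synthetic_dis3_like("+")
        skip = model_exon_skip(ex.transcript, ex.skip_exon_tx_index, ex.genome)
        # anchor residue Arg is preserved (Arg557Argfs*3) yet still reported
        assert skip.first_affected_codon == 557
        assert skip.hgvs_p.startswith("p.Arg557Arg")


class TestNmd:
    def _model(self):
        # two coding exons; exon 1 contributes 125 coding nt, so codon 26
        # (first nt at CDS offset 75, 0-based) sits exactly 50 nt upstream
        # of the single exon-exon junction
        ex1 = "ATG" + "GAA" * 40 + "GA"  # 125 nt
        ex2 = "A" + "GAA" * 18 + "TAA"  # 58 nt, restores the frame
        return make_gene([ex1, ex2])

    def test_ptc_in_last_exon_is_false(self):
        genome, model = self._model()
        assert predict_nmd(model, 44) is False  # codon 44 starts in exon 2

    def test_exactly_50nt_upstream_is_true(self):
        genome, model = self._model()
        assert predict_nmd(model, 26) is True  # exactly 50 nt upstream
        assert predict_nmd(model, 27) is False  # 47 nt upstream

    def test_monotone_upstream(self):
        genome, model = self._model()
        values = [predict_nmd(model, c) for c in range(1, 41)]
        # once False moving downstream, never True again
        assert values == sorted(values, reverse=True)

    def test_single_exon_always_false(self, toy_single_exon):
        genome, model = toy_single_exon
        assert predict_nmd(model, 1) is False

    def test_worked_example_skip_is_nmd(self):
        ex = synthetic_dis3_like("+")
        skip = model_exon_skip(ex.transcript, ex.skip_exon_tx_index, ex.genome)
        assert skip.ptc_codon == 559
        assert skip.nmd_predicted is True


class TestReadthrough:
    def test_utr_with_immediate_stop_gives_zero(self):
        ex1 = "ATGGCTGAAACCGGTGCTTAA"
        genome, model = make_gene([ex1], utr3="TGACCCGGG")
        pos = model.cds_end_g - 2  # first base of TAA
        rt = extend_readthrough(Variant("chrT", pos, "T", "C"), model, genome)
        assert rt.extension_residues == 0
        assert rt.new_stop_found

    def test_two_codons_then_stop(self):
        genome, model = make_gene(["ATGGCTGAAACCGGTGCTTAA"], utr3="CAACAATGAGGG")
        pos = model.cds_end_g - 2
        rt = extend_readthrough(Variant("chrT", pos, "T", "C"), model, genome)
        assert rt.substituted_residue == "Q"  # CAA
        assert rt.extension_residues == 2
        assert rt.new_stop_found

    def test_no_stop_in_transcript_flagged(self):
        genome, model = make_gene(["ATGGCTGAAACCGGTGCTTAA"], utr3="CAACAACAACCC")
        pos = model.cds_end_g - 2
        rt = extend_readthrough(Variant("chrT", pos, "T", "C"), model, genome)
        assert not rt.new_stop_found

    def test_not_overlapping_stop_raises(self, toy_three_exon):
        genome, model = toy_three_exon
        with pytest.raises(ValueError):
            extend_readthrough(
                Variant("chrT", model.cds_start_g, "A", "G"), model, genome
            )

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_strand_invariance(self, strand):
        """Re-embedding the same transcript reverse-complemented leaves the
        extension length unchanged."""
        ex = synthetic_dis3_like(strand)
        rt = extend_readthrough(ex.stop_loss_variant, ex.transcript, ex.genome)
        assert rt.substituted_residue == "Q"
        assert rt.extension_residues == 13
        assert rt.new_stop_found


class TestWorkedExample:
    """The synthetic surrogate reproduces the published coordinate
    arithmetic end to end."""

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_splice_variant_names_and_skip(self, strand):
        ex = synthetic_dis3_like(strand)
        call = classify(ex.splice_donor_variant, ex.transcript, ex.genome)
        assert call.klass == "splice_donor"
        assert call.hgvs_c == "c.1755+1G>T"
        assert call.hgvs_p == "p.Arg557Argfs*3"
        assert call.ptc_codon == 559
        assert call.nmd_predicted is True
        assert call.is_truncating

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_stop_loss_extension(self, strand):
        ex = synthetic_dis3_like(strand)
        call = classify(ex.stop_loss_variant, ex.transcript, ex.genome)
        assert call.klass == "stop_loss"
        assert call.hgvs_c == "c.2875T>C"
        assert call.hgvs_p == "p.*959Glnext*14"
        assert call.extension_residues == 13


class TestLofGate:
    def _call(self, klass):
        v = Variant("chrT", 1, "A", "C")
        return ConsequenceCall(v, "t", "g", klass)

    @pytest.mark.parametrize(
        "klass", ["stop_gain", "frameshift", "splice_donor", "splice_acceptor", "stop_loss"]
    )
    def test_truncating_always_qualifies(self, klass):
        assert is_putative_lof(self._call(klass)) is True

    def test_synonymous_never_qualifies_even_with_high_score(self):
        assert is_putative_lof(self._call("synonymous"), 99.0) is False

    def test_missense_inclusive_threshold(self):
        assert is_putative_lof(self._call("missense"), 20.0) is True
        assert is_putative_lof(self._call("missense"), 19.99) is False
        assert (
            is_putative_lof(
                self._call("missense"), 15.0, LofConfig(missense_score_threshold=15)
            )
            is True
        )

    def test_missense_without_score_warns_false(self):
        with pytest.warns(UserWarning):
            assert is_putative_lof(self._call("missense"), None) is False
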