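import numpy as np
import pytest

from _oracles import random_dna
from smorfkit.classify import (
    back_correlate,
    classify,
    compute_coverage,
    summarize_seps,
)
from smorfkit.genome import AnnotationRecord, SequenceRecord, revcomp
from smorfkit.mapping import MapperPolicy, filter_hits, map_peptide
from smorfkit.reports import percent
from smorfkit.simulate import _encode


def build_genome(parts):
    """Concatenate parts; return (SequenceRecord, dict of part -> 1-based start)."""
    pos = {}
    cursor = 1
    chunks = []
    for name, s in parts:
        pos[name] = cursor
        chunks.append(s)
        cursor += len(s)
    return SequenceRecord("chr", "".join(chunks)), pos


def one_locus(pep, genome, max_mismatch=0):
    policy = MapperPolicy(max_mismatch=max_mismatch)
    loci = filter_hits(map_peptide(pep, genome, policy), policy)
    assert len(loci) == 1, loci
    return loci[0]


class TestBackCorrelate:
    def test_minus_strand_99aa_sep_from_nterminal_peptide(self):
        # a 300-nt ORF (99 aa) on the minus strand, peptide at its ATG start
        rng = np.random.default_rng(0)
        body = _encode(rng, "RFPGGGE" + "".join(rng.choice(list("ADGHKNQSTW"), 91)), safe=False)
        orf_nt = "ATG" + body + "TGA"
        assert len(orf_nt) == 300
        genome, pos = build_genome(
            [("l", random_dna(rng, 51)), ("orf", revcomp("TAA" + orf_nt)), ("r", random_dna(rng, 51))]
        )
        locus = one_locus("MRFPGGGE", genome)
        bc = back_correlate(locus, genome)
        assert not bc.orphan
        assert bc.sep_length == 99
        assert bc.chosen_start.codon == "ATG"
        assert bc.sep_interval.length == 300  # span includes the stop codon
        assert bc.orf.strand == "-"

    def test_hidden_internal_start_under_length_cap(self):
        # peptide inside the C-terminal window of a 120-aa frame whose only
        # start within the 100-aa cap is an internal GTG 24 codons upstream
        rng = np.random.default_rng(1)
        upstream = _encode(rng, "".join(rng.choice(list("ADGHKNQSTW"), 95)), safe=True)
        isep_body = _encode(rng, "GAGPGEGDDAVRPGFHK" + "".join(rng.choice(list("ADGHKNQSTW"), 6)), safe=False)
        orf_nt = "ATG" + upstream + "GTG" + isep_body + "TAA"
        genome, pos = build_genome(
            [("l", random_dna(rng, 30)), ("orf", "TAA" + orf_nt), ("r", random_dna(rng, 30))]
        )
        locus = one_locus("VGAGPGEGDDAVRPG", genome)
        bc = back_correlate(locus, genome, max_aa=100)
        assert bc.sep_length == 24
        assert bc.chosen_start.codon == "GTG"

    def test_orphan_when_no_start_upstream(self):
        rng = np.random.default_rng(2)
        pep = "DDNKHTREF"  # no residue can sit on a start codon
        nt = _encode(rng, pep, safe=True)
        genome, _ = build_genome(
            [("l", random_dna(rng, 33)), ("cassette", "TAA" + nt + "TAA"), ("r", random_dna(rng, 33))]
        )
        locus = one_locus(pep, genome)
        bc = back_correlate(locus, genome)
        assert bc.orphan and "start" in bc.reason

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        pep = "MKDNWHTREF"
        nt = _encode(rng, pep, safe=False)
        genome, _ = build_genome([("x", "TAA" + nt + "TAA")])
        locus = one_locus(pep, genome)
        assert back_correlate(locus, genome) == back_correlate(locus, genome)


class TestClassify:
    def _fixture(self, rng, strand="+"):
        """Genome with an annotated 120-aa CDS holding a hidden-GTG 24-aa tail."""
        upstream = _encode(rng, "".join(rng.choice(list("ADGHKNQSTW"), 95)), safe=True)
        tail = _encode(rng, "GAGPGEGDDAVRPGFHKWDNATQ", safe=False)
        orf_nt = "ATG" + upstream + "GTG" + tail + "TAA"
        d = "TAA" + orf_nt if strand == "+" else revcomp("TAA" + orf_nt)
        genome, pos = build_genome(
            [("l", random_dna(rng, 33)), ("ins", d), ("r", random_dna(rng, 33))]
        )
        if strand == "+":
            cds = AnnotationRecord("chr", pos["ins"] + 3, pos["ins"] + 3 + len(orf_nt) - 1, "+", "RS26880")
        else:
            cds = AnnotationRecord("chr", pos["ins"], pos["ins"] + len(orf_nt) - 1, "-", "RS26880")
        return genome, cds

    def test_exact_cds_coincidence_is_annotated(self):
        rng = np.random.default_rng(4)
        pep = "MKDNWHTREFA"
        nt = _encode(rng, pep, safe=False)
        orf_nt = "ATG" + nt[3:] + "TAA"
        genome, pos = build_genome([("l", random_dna(rng, 33)), ("ins", "TAA" + orf_nt)])
        cds = AnnotationRecord("chr", pos["ins"] + 3, pos["ins"] + 3 + len(orf_nt) - 1, "+", "g1")
        locus = one_locus(pep, genome)
        call = classify(back_correlate(locus, genome), [cds], len(genome.residues), [locus])
        assert call.sep_class == "annotated"
        assert call.parent_feature.feature_id == "g1"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_shared_stop_internal_start_is_isep(self, strand):
        rng = np.random.default_rng(5)
        genome, cds = self._fixture(rng, strand)
        locus = one_locus("VGAGPGEGDDAVRPG", genome)
        call = classify(back_correlate(locus, genome), [cds], len(genome.residues), [locus])
        assert call.sep_class == "ISEP"
        assert call.sep_length == 24
        assert call.parent_feature.feature_id == "RS26880"
        assert ("RS26880", "shared_stop") in [
            (f.feature_id, rel) for f, rel in call.overlapping_features
        ]

    def test_opposite_strand_overlap_is_csep_with_note(self):
        rng = np.random.default_rng(6)
        pep = "MRFPGGGEQ"
        nt = _encode(rng, pep, safe=False)
        genome, pos = build_genome([("l", random_dna(rng, 33)), ("ins", "TAA" + "ATG" + nt[3:] + "TAA")])
        # annotate an overlapping gene on the other strand
        other = AnnotationRecord("chr", pos["ins"], pos["ins"] + 50, "-", "RS03870")
        locus = one_locus(pep, genome)
        call = classify(back_correlate(locus, genome), [other], len(genome.residues), [locus])
        assert call.sep_class == "CSEP"
        assert ("RS03870", "opposite_strand_overlap") in [
            (f.feature_id, rel) for f, rel in call.overlapping_features
        ]
        assert any("isoform_like_overlap" in n for n in call.notes)

    def test_intergenic_is_csep(self):
        rng = np.random.default_rng(7)
        pep = "MRFPGGGEQ"
        nt = _encode(rng, pep, safe=False)
        genome, _ = build_genome([("ins", "TAA" + "ATG" + nt[3:] + "TAA")])
        locus = one_locus(pep, genome)
        call = classify(back_correlate(locus, genome), [], len(genome.residues), [locus])
        assert call.sep_class == "CSEP" and not call.overlapping_features


class TestCoverage:
    def _call(self, rng, pep="MKDNWHTREFAGQSVVPW"):
        nt = _encode(rng, pep, safe=False)
        genome, _ = build_genome([("ins", "TAA" + "ATG" + nt[3:] + "TAA")])
        locus = one_locus(pep, genome)
        call = classify(back_correlate(locus, genome), [], len(genome.residues), [locus])
        return genome, call

    def test_no_peptides_zero(self):
        rng = np.random.default_rng(8)
        genome, call = self._call(rng)
        prof = compute_coverage(call, [], genome)
        assert prof.coverage_pct == 0.0 and not prof.full_length

    def test_union_not_sum(self):
        rng = np.random.default_rng(9)
        pep = "MKDNWHTREFAGQSVVPWDD"  # 20 aa
        genome, call = self._call(rng, pep)
        loci = [one_locus(pep[:10], genome), one_locus(pep[4:], genome)]
        prof = compute_coverage(call, loci, genome)
        assert prof.coverage_pct == 100.0 and prof.full_length and prof.n_term_excised is None

    def test_met_excision_full_length(self):
        rng = np.random.default_rng(10)
        pep = "MKDNWHTREFAGQSVVPWDD"
        genome, call = self._call(rng, pep)
        prof = compute_coverage(call, [one_locus(pep[1:], genome)], genome)
        assert prof.full_length and prof.n_term_excised == "M"
        assert prof.coverage_pct == percent(19, 20)

    def test_duplicate_and_order_invariance(self):
        rng = np.random.default_rng(11)
        pep = "MKDNWHTREFAGQSVVPWDD"
        genome, call = self._call(rng, pep)
        a, b = one_locus(pep[:10], genome), one_locus(pep[4:], genome)
        p1 = compute_coverage(call, [a, b], genome)
        p2 = compute_coverage(call, [b, a, b], genome)
        assert p1 == p2

    def test_outside_peptide_is_hard_error(self):
        rng = np.random.default_rng(12)
        pep = "MKDNWHTREFAGQSVVPW"
        other_pep = "WWDNKHTRE"
        sep_nt = "ATG" + _encode(rng, pep, safe=False)[3:] + "TAA"
        other_nt = _encode(rng, other_pep, safe=False)
        genome, _ = build_genome(
            [("sep", "TAA" + sep_nt), ("gap", random_dna(rng, 30)), ("other", "TAA" + other_nt + "TAA")]
        )
        locus = one_locus(pep, genome)
        call = classify(back_correlate(locus, genome), [], len(genome.residues), [locus])
        outside = one_locus(other_pep, genome)
        with pytest.raises(ValueError):
            compute_coverage(call, [outside], genome)


class TestSummaries:
    def test_bookkeeping_percentages(self):
        assert percent(3, 126) == 2.38
        assert percent(109, 126, 1) == 86.5

    def test_empty_inputs_give_empty_tables(self):
        tables = summarize_seps([], [])
        assert tables["length_bins"]["count"].sum() == 0
        assert tables["classes"]["count"].sum() == 0
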