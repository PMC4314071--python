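import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yeastprimers import (
    ChromosomeRecord,
    DesignError,
    DesignParams,
    GenomicFeature,
    attach_tail,
    build_catalog,
    design_ctag_forward,
    design_deletion_forward,
    design_primer_set,
    design_reverse,
    genome_index,
    reverse_complement,
    sense_flank,
)

N6 = DesignParams(homology_length=6, ftype="CDS")
N6_NC = DesignParams(homology_length=6, ftype="ncRNA")


def as_ncrna(feature):
    return dataclasses.replace(feature, ftype="ncRNA")


# --- flank extraction -------------------------------------------------------

def test_upstream_flank_plus_strand(toy_genome, toy_cds_plus):
    assert sense_flank(toy_genome, toy_cds_plus, "upstream", 3) == "CGT"


def test_upstream_flank_minus_strand_is_reverse_complemented(toy_genome, toy_cds_minus):
    assert sense_flank(toy_genome, toy_cds_minus, "upstream", 3) == "CAA"


def test_flank_beyond_chromosome_start_is_padded(toy_genome):
    feat = GenomicFeature(
        chrom_id="chr1", start=1, end=9, systematic_name="f",
        common_name="", strand="+", ftype="CDS",
    )
    assert sense_flank(toy_genome, feat, "upstream", 7) == "NNNNNNN"


def test_flank_unknown_chromosome_is_fatal(toy_genome, toy_cds_plus):
    lost = dataclasses.replace(toy_cds_plus, chrom_id="chr9")
    with pytest.raises(DesignError, match="chr9"):
        sense_flank(toy_genome, lost, "upstream", 3)


# --- reverse complement -----------------------------------------------------

@pytest.mark.parametrize("seq, expected", [("ACGT", "ACGT"), ("", ""), ("TAGTTG", "CAACTA")])
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_reports_bad_character_position():
    with pytest.raises(DesignError, match="position 3"):
        reverse_complement("ACXGT")


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="ACGTN", max_size=200))
def test_reverse_complement_involution_and_length(seq):
    assert reverse_complement(reverse_complement(seq)) == seq
    assert len(reverse_complement(seq)) == len(seq)


# --- primer geometry on the toy ORFs ---------------------------------------

def test_deletion_forward_ends_with_start_codon(toy_genome, toy_cds_plus, toy_cds_minus):
    assert design_deletion_forward(toy_cds_plus, toy_genome, N6) == "CGTATG"
    assert design_deletion_forward(toy_cds_minus, toy_genome, N6) == "CAAATG"


def test_deletion_forward_noncoding_rule(toy_genome, toy_cds_plus):
    assert design_deletion_forward(as_ncrna(toy_cds_plus), toy_genome, N6_NC) == "GTACGT"


def test_ctag_forward_ends_at_last_codon_before_stop(toy_genome, toy_cds_plus, toy_cds_minus):
    assert design_ctag_forward(toy_cds_plus, toy_genome, N6) == "ATGAAA"
    assert design_ctag_forward(toy_cds_minus, toy_genome, N6) == "ATGCCC"
    assert design_ctag_forward(toy_cds_plus, toy_genome, DesignParams(4)) == "GAAA"


def test_ctag_requires_cds(toy_genome, toy_cds_plus):
    with pytest.raises(DesignError):
        design_ctag_forward(as_ncrna(toy_cds_plus), toy_genome, N6_NC)


def test_reverse_primer_examples(toy_genome, toy_cds_plus, toy_cds_minus):
    assert design_reverse(toy_cds_plus, toy_genome, N6) == "CAACTA"
    # minus-strand reverse equals the plus strand 6-11: strand-consistency check
    assert design_reverse(toy_cds_minus, toy_genome, N6) == "CGTTTA"
    assert design_reverse(as_ncrna(toy_cds_plus), toy_genome, N6_NC) == "GGCCAA"


# --- tails ------------------------------------------------------------------

@pytest.mark.parametrize(
    "arm, mode, expected",
    [
        ("CGTATG", "fwd_standard", "CGTATGCGGATCCCCGGGTTAATTAA"),
        ("CAACTA", "rev", "CAACTAGAATTCGAGCTCGTTTAAAC"),
        ("GTACGT", "fwd_utr", "GTACGTGCGAATTTCTTATGATTTATG"),
    ],
)
def test_attach_tail_appends_constant_priming_site(arm, mode, expected):
    assert attach_tail(arm, mode) == expected


def test_tailed_deletion_forward(toy_genome, toy_cds_plus):
    ps = design_primer_set(toy_cds_plus, toy_genome, N6)
    assert ps.fwd_del_tailed == "CGTATGCGGATCCCCGGGTTAATTAA"


def test_homology_below_four_rejected():
    with pytest.raises(DesignError):
        DesignParams(homology_length=3)


# --- invariants at scale ----------------------------------------------------

@pytest.mark.parametrize("n", [4, 6, 50, 80])
def test_length_law_holds_including_padded_features(small_syn, n, request):
    """Every untailed arm has length exactly N, even at chromosome ends."""
    for code in ("CDS", "ncRNA", "3UTR", "tRNA"):
        params = DesignParams(homology_length=n, ftype=code)
        for feat in build_catalog(small_syn.records, code):
            ps = design_primer_set(feat, small_syn.index, params)
            assert len(ps.fwd_del) == n
            assert len(ps.rev) == n
            if code == "CDS":
                assert len(ps.fwd_tag) == n
            assert ps.fwd_del_tailed == ps.fwd_del + (
                "GCGAATTTCTTATGATTTATG" if code == "3UTR" else "CGGATCCCCGGGTTAATTAA"
            )
            assert ps.rev_tailed == ps.rev + "GAATTCGAGCTCGTTTAAAC"


def test_strand_duality(small_syn):
    """Mirroring the genome (reverse complement + flipped coordinates and
    strand) leaves every primer unchanged."""
    mirrored = genome_index(
        ChromosomeRecord(c.id, reverse_complement(c.sequence), c.length)
        for c in small_syn.chromosomes
    )
    params = DesignParams(homology_length=50, ftype="CDS")
    for feat in build_catalog(small_syn.records, "CDS"):
        length = small_syn.index[feat.chrom_id].length
        twin = dataclasses.replace(
            feat,
            start=length - feat.end + 1,
            end=length - feat.start + 1,
            strand="-" if feat.strand == "+" else "+",
        )
        original = design_primer_set(feat, small_syn.index, params)
        flipped = design_primer_set(twin, mirrored, params)
        assert (original.fwd_del, original.fwd_tag, original.rev) == (
            flipped.fwd_del, flipped.fwd_tag, flipped.rev,
        )
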