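"""TIS scanning, ORF extension and upORF typing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utrsat import (
    TranscriptModel,
    extend_orf,
    reference_uporfs,
    scan_tis,
)
from utrsat.orf import NEAR_COGNATE_TIS, TisSite, tis_created
from utrsat.synthetic import ToySpec, random_transcript


class TestScan:
    @pytest.fixture
    def t7(self):
        return TranscriptModel(id="t7", utr5="ACGATGC", cds="ATGAAATGA")

    def test_canonical_only(self, t7):
        sites = scan_tis(t7, tis_mode="canonical")
        assert [(s.c_start, s.codon) for s in sites] == [(-4, "ATG")]

    def test_both_modes_include_near_cognates(self, t7):
        sites = scan_tis(t7, tis_mode="both")
        assert [(s.c_start, s.codon) for s in sites] == [(-7, "ACG"), (-4, "ATG")]

    def test_empty_when_no_tis(self):
        t = TranscriptModel(id="t", utr5="CCCCCCC", cds="ATGAAATGA")
        # windows crossing into the CDS pick up the main ATG context only
        sites = scan_tis(t, region=(-7, -4), tis_mode="both")
        assert sites == []

    def test_near_cognate_set_is_one_mismatch_from_atg(self):
        assert len(NEAR_COGNATE_TIS) == 9
        for codon in NEAR_COGNATE_TIS:
            assert sum(a != b for a, b in zip(codon, "ATG")) == 1


class TestTisCreated:
    @pytest.mark.parametrize(
        "ref, alt, created",
        [
            ("CCG", "CTG", True),  # none -> near-cognate
            ("ATA", "ATG", True),  # near-cognate -> canonical upgrade
            ("ATC", "ATA", True),  # new near-cognate identity
            ("ATG", "ATA", False),  # downgrade from AUG is a loss, not a gain
            ("CCC", "CCA", False),
        ],
    )
    def test_identity_rule(self, ref, alt, created):
        assert tis_created(ref, alt, "both") is created

    def test_canonical_mode_ignores_near_cognates(self):
        assert not tis_created("CCG", "CTG", "canonical")
        assert tis_created("ATA", "ATG", "canonical")


class TestExtend:
    def test_uorf_fully_inside_utr(self):
        t = TranscriptModel(id="t", utr5="ATGTAAC", cds="ATGAAATGA")
        orf = extend_orf(t, TisSite(-7, "ATG", True))
        assert (orf.orf_type, orf.stop_c_start, orf.length_nt) == ("uORF", -4, 6)

    def test_in_frame_tis_runs_to_main_stop(self):
        t = TranscriptModel(id="t", utr5="ATGCAA", cds="ATGAAATGA")
        orf = extend_orf(t, TisSite(-6, "ATG", True))
        assert orf.orf_type == "eCDS"
        assert orf.ends_at_main_stop
        assert orf.length_nt == 6 + 9

    def test_out_of_frame_tis_stops_inside_cds(self):
        # CTG at c.-7 (frame 2) reads to the TGA spanning c.6-8, upstream
        # of the main stop -> overlapping upORF
        t = TranscriptModel(id="t", utr5="CTGCCCC", cds="ATGACTGACTAA")
        orf = extend_orf(t, TisSite(-7, "CTG", False))
        assert (orf.orf_type, orf.stop_c_start, orf.length_nt) == ("uoORF", 6, 15)
        assert not orf.ends_at_main_stop

    def test_no_stop_returns_none(self):
        # ATG at c.-5: its frame meets no stop triplet before the last
        # full window of the transcript
        t = TranscriptModel(id="t", utr5="CATGCC", cds="ATGCAAGGGTAA")
        assert extend_orf(t, TisSite(-5, "ATG", True)) is None

    def test_eng_cug_to_c125(self, eng):
        orf = extend_orf(eng, TisSite(-77, "CTG", False))
        assert (orf.orf_type, orf.stop_c_start, orf.length_nt) == ("uoORF", 125, 204)


class TestReferenceLandscape:
    def test_two_tis_can_share_one_stop(self):
        t = TranscriptModel(id="t", utr5="ATGATGTAAC", cds="ATGAAATGA")
        orfs = reference_uporfs(t, tis_mode="canonical")
        assert len(orfs) == 2
        assert {o.stop_c_start for o in orfs} == {-4}

    def test_empty_without_tis(self):
        t = TranscriptModel(id="t", utr5="CCCCCCCCC", cds="ATGAAATGA")
        assert reference_uporfs(t, tis_mode="canonical") == []

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None)
    def test_invariants_on_random_transcripts(self, seed):
        t = random_transcript(ToySpec(seed=seed, utr5_len=40, cds_codons=8))
        for orf in reference_uporfs(t, tis_mode="both"):
            assert orf.length_nt % 3 == 0
            in_frame = abs(orf.tis.c_start) % 3 == 0
            if orf.orf_type == "eCDS":
                assert in_frame and orf.ends_at_main_stop
            if in_frame:
                # frame-0 starts either reach the main stop or hit a
                # frame-0 stop still inside the 5'UTR
                assert orf.orf_type in {"eCDS", "uORF"}
            if orf.orf_type == "uORF":
                assert orf.stop_c_start + 2 < 0  # stop entirely in the UTR
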