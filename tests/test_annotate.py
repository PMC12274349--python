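"""Per-variant delta annotation and catalog assembly."""

import pytest

from utrsat import (
    TranscriptModel,
    annotate_variant,
    build_catalog,
    make_snv,
    read_catalog,
    resolve_stop_deletion,
    write_catalog,
)
from utrsat.orf import TisSite, extend_orf
from utrsat.transcript import CoordinateError


def consequences(recs):
    return sorted(r.consequence for r in recs)


class TestTisCreation:
    def test_cug_creating_variant_on_eng(self, eng):
        recs = annotate_variant(eng, make_snv(eng, -76, "T"))
        assert len(recs) == 1
        r = recs[0]
        assert r.consequence == "uTIS_created"
        assert (r.created_tis.c_start, r.created_tis.codon) == (-77, "CTG")
        assert (r.uporf.orf_type, r.uporf.stop_c_start, r.uporf.length_nt) == (
            "uoORF",
            125,
            204,
        )
        assert (r.kozak.sevenmer, r.kozak.strength) == ("ACGCTGG", "strong")

    def test_variant_creating_two_tis(self, eng):
        # one substitution can upgrade one window to AUG and give another
        # window a new near-cognate identity at the same time
        recs = annotate_variant(eng, make_snv(eng, -287, "A"))
        created = {(r.created_tis.c_start, r.created_tis.codon) for r in recs}
        assert created == {(-287, "ATG"), (-289, "ATA")}
        by_tis = {r.created_tis.c_start: r.uporf for r in recs}
        assert by_tis[-287].orf_type == "uoORF" and by_tis[-287].stop_c_start == 125
        assert by_tis[-289].orf_type == "uORF" and by_tis[-289].stop_c_start == -166

    def test_downgrade_from_aug_is_not_a_creation(self):
        t = TranscriptModel(id="t", utr5="CCCATGCCC", cds="ATGCAAGGGTAA")
        recs = annotate_variant(t, make_snv(t, -5, "A"))  # ATG -> AAG
        assert consequences(recs) == []

    def test_silent_snv_yields_empty_list(self, eng):
        assert annotate_variant(eng, make_snv(eng, -100, "C")) == []

    def test_cds_variant_rejected(self, eng):
        with pytest.raises(CoordinateError, match="5'UTR"):
            annotate_variant(eng, make_snv(eng, 10, "A"))


class TestStopCreation:
    def test_multi_consequence_variant(self, eng):
        # creates a uAUG-uoORF and a TGA stop three codons before the TAA
        # at c.-34, shortening the upORFs that ended there
        recs = annotate_variant(eng, make_snv(eng, -37, "T"))
        classes = set(consequences(recs))
        assert classes == {"uTIS_created", "uStop_created"}
        stop_recs = [r for r in recs if r.consequence == "uStop_created"]
        assert all(r.stop_c == -37 for r in stop_recs)
        assert all(r.is_shortening for r in stop_recs)
        assert all(r.affected_ref_uporf.stop_c_start == -34 for r in stop_recs)
        assert all(r.uporf.stop_c_start == -37 for r in stop_recs)

    def test_orphan_stop_suppressed_by_default(self):
        # TAA created in a frame with no upstream TIS at all
        t = TranscriptModel(id="t", utr5="CCCCTCACCC", cds="ATGCAAGGGTAA")
        snv = make_snv(t, -5, "A")  # TCA -> TAA at c.-6..-4
        assert annotate_variant(t, snv) == []
        orphan = annotate_variant(t, snv, report_orphan_stops=True)
        assert consequences(orphan) == ["uStop_created"]
        assert orphan[0].uporf is None and orphan[0].stop_c == -6

    def test_new_stop_linked_to_upstream_tis_defines_new_uporf(self):
        # in-frame ATG at c.-12 previously ran to the main stop (eCDS);
        # the created frame-0 TAA inside the UTR carves out a new uORF
        t = TranscriptModel(id="t", utr5="ATGAAATCACCC", cds="ATGCAAGGGTAA")
        recs = annotate_variant(t, make_snv(t, -5, "A"))
        stop_recs = [r for r in recs if r.consequence == "uStop_created"]
        assert len(stop_recs) == 1
        r = stop_recs[0]
        assert r.affected_ref_uporf.ends_at_main_stop
        assert r.is_shortening is False
        assert (r.uporf.orf_type, r.uporf.stop_c_start, r.uporf.length_nt) == (
            "uORF",
            -6,
            9,
        )


class TestStopDeletion:
    @pytest.fixture
    def t_uorf(self):
        # uORF: ATG at c.-13 (frame 2), TAA at c.-7; after deleting the
        # TAA the walk continues to the TGA spanning c.6-8 inside the CDS
        return TranscriptModel(id="t", utr5="CATGAAATAACCCC", cds="ATGACTGACTAA")

    def test_deletion_elongates_into_cds(self, t_uorf):
        recs = annotate_variant(t_uorf, make_snv(t_uorf, -7, "C"))  # TAA -> CAA
        assert consequences(recs) == ["uStop_deleted"]
        r = recs[0]
        assert r.affected_ref_uporf.stop_c_start == -7
        assert r.affected_ref_uporf.orf_type == "uORF"
        assert (r.uporf.orf_type, r.uporf.stop_c_start) == ("uoORF", 6)

    def test_stop_to_stop_change_is_not_a_deletion(self, t_uorf):
        recs = annotate_variant(t_uorf, make_snv(t_uorf, -5, "G"))  # TAA -> TAG
        assert recs == []

    def test_resolve_stop_deletion_rejects_non_deleters(self, t_uorf):
        ref_orf = extend_orf(t_uorf, TisSite(-13, "ATG", True))
        with pytest.raises(ValueError, match="does not delete"):
            resolve_stop_deletion(t_uorf, make_snv(t_uorf, -5, "G"), ref_orf)

    def test_eng_stop_deleters_elongate_to_published_landscape(self, eng):
        # deleting the TGA at c.-166 elongates its uORFs to the TAA at c.-34
        recs = annotate_variant(eng, make_snv(eng, -166, "C"))  # TGA -> CGA
        dels = [r for r in recs if r.consequence == "uStop_deleted"]
        assert dels, recs
        assert all(r.uporf.stop_c_start == -34 for r in dels)
        # deleting the TAA at c.-34 elongates into the CDS, to the stop at c.90
        recs = annotate_variant(eng, make_snv(eng, -34, "C"))
        dels = [r for r in recs if r.consequence == "uStop_deleted"]
        assert dels
        assert all(
            (r.uporf.orf_type, r.uporf.stop_c_start) == ("uoORF", 90) for r in dels
        )


class TestCatalog:
    def test_partition_identities_and_structure(self, eng):
        cat = build_catalog(eng)
        s = cat.summary
        assert s["n_snvs"] == 909
        assert (
            s["n_pure_uTIS"] + s["n_pure_uStop_new"] + s["n_pure_uStop_del"] + s["n_multi"]
            == s["n_annotated"]
        )
        assert s["n_uORF"] + s["n_uoORF"] + s["n_eCDS"] == s["n_uporfs_uTIS_created"]
        # every uTIS-created ORF ends at one of the landscape stops
        assert set(s["stop_position_tally"]) <= {
            "uORF@c.-166",
            "uORF@c.-34",
            "uoORF@c.90",
            "uoORF@c.125",
            "eCDS@main",
        }

    def test_catalog_empty_on_inert_utr(self):
        # poly-C UTR: no window can gain a TIS or a stop with one change...
        t = TranscriptModel(id="t", utr5="CCCCCCCCC", cds="ATGCAAGGGTAA")
        cat = build_catalog(t, region=(-9, -7))
        assert cat.summary["n_annotated"] == 0

    def test_write_read_round_trip(self, eng, tmp_path):
        cat = build_catalog(eng, region=(-80, -70))
        tsv, vcf = write_catalog(cat, tmp_path / "eng_catalog", t=eng)
        df = read_catalog(tsv)
        assert len(df) == len(cat.records)
        back = df.to_dict("records")
        orig = cat.to_dataframe().to_dict("records")
        for a, b in zip(orig, back):
            for key, val in a.items():
                if val is None:
                    assert b[key] is None or b[key] != b[key]  # NaN
                else:
                    assert b[key] == val, key
        text = vcf.read_text()
        assert "UTRSAT_CSQ=" in text and "c.-76C>T" in text

    def test_empty_catalog_writes_header_only(self, tmp_path):
        t = TranscriptModel(id="t", utr5="CCCCCCCCC", cds="ATGCAAGGGTAA")
        cat = build_catalog(t, region=(-9, -7))
        tsv, _ = write_catalog(cat, tmp_path / "empty")
        lines = tsv.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("hgvs_c\t")
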