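"""Junction placement tags, host selection, RPKM and junction insertion."""

import pytest

from spliceneo.isoforms import (
    Rejected,
    classify_placement,
    compute_rpkm,
    insert_junction,
    map_junction_to_isoforms,
    select_hosts,
)
from spliceneo.junctions import Junction
from spliceneo.models import TranscriptModel


def _j(start, end, strand="+", reads=100):
    return Junction("chrT", strand, start, end, reads)


class TestClassification:
    def test_annotated_intron_is_tag0(self, toy_model):
        assert classify_placement(_j(200, 300), toy_model).tag == 0

    def test_exon_skip_is_tag1(self, toy_model):
        p = classify_placement(_j(200, 500), toy_model)
        assert p.tag == 1
        assert p.donor_site_kind == p.acceptor_site_kind == "annotated_boundary"

    def test_one_novel_site_is_tag2(self, toy_model):
        p = classify_placement(_j(200, 350), toy_model)
        assert p.tag == 2
        assert p.acceptor_site_kind == "novel"

    def test_both_novel_is_tag3(self, toy_model):
        assert classify_placement(_j(320, 380), toy_model).tag == 3

    def test_donor_acceptor_kinds_flip_on_minus_strand(self, toy_model):
        minus = TranscriptModel(
            "TOYM", "G", "chrT", "-", toy_model.exons, toy_model.cds_start, toy_model.cds_end
        )
        p = classify_placement(_j(200, 350, strand="-"), minus)
        # genomic-left site is annotated; on '-' that is the acceptor
        assert p.acceptor_site_kind == "annotated_boundary"
        assert p.donor_site_kind == "novel"


class TestMapping:
    def test_junction_outside_span_not_placed(self, toy_model):
        assert map_junction_to_isoforms(_j(50, 150), [toy_model]) == []

    def test_strand_mismatch_not_placed(self, toy_model):
        assert map_junction_to_isoforms(_j(200, 300, strand="-"), [toy_model]) == []

    def test_unknown_strand_placed_on_both(self, toy_model):
        minus = TranscriptModel(
            "TOYM", "G", "chrT", "-", toy_model.exons, toy_model.cds_start, toy_model.cds_end
        )
        placements = map_junction_to_isoforms(_j(200, 300, strand="."), [toy_model, minus])
        assert {p.host.transcript_id for p in placements} == {"TOY1", "TOYM"}


class TestHostSelection:
    def test_smallest_tag_wins(self, toy_model):
        p1 = classify_placement(_j(200, 500), toy_model)  # tag 1
        p2 = classify_placement(_j(200, 350), toy_model)  # tag 2
        rpkm = {"TOY1": 10.0}
        assert select_hosts([p1, p2, p2], rpkm) == [p1]

    def test_rpkm_gate_is_strict(self, toy_model):
        p1 = classify_placement(_j(200, 500), toy_model)
        assert select_hosts([p1], {"TOY1": 1.0}) == []
        assert select_hosts([p1], {"TOY1": 1.01}) == [p1]
        assert select_hosts([p1], {}) == []  # missing -> 0

    def test_any_tag0_placement_suppresses_novel_isoforms(self, toy_model):
        p0 = classify_placement(_j(200, 300), toy_model)
        p2 = classify_placement(_j(200, 350), toy_model)
        assert select_hosts([p0, p2], {"TOY1": 10.0}) == []


class TestRpkm:
    def test_formula(self, toy_model):
        model = TranscriptModel("T", "G", "c", "+", ((0, 1000),), 0, 999)
        assert compute_rpkm(model, 1000, 10_000_000) == pytest.approx(100.0)

    def test_zero_reads(self, toy_model):
        assert compute_rpkm(toy_model, 0, 1_000_000) == 0.0

    def test_doubling_total_halves_rpkm(self, toy_model):
        one = compute_rpkm(toy_model, 500, 1_000_000)
        two = compute_rpkm(toy_model, 500, 2_000_000)
        assert one == pytest.approx(2 * two)


class TestInsertion:
    def test_tag1_skip_removes_interior_exon_only(self, toy_model):
        p = classify_placement(_j(200, 500), toy_model)
        iso = insert_junction(p)
        assert iso.exons == ((100, 200), (500, 560), (700, 800))
        assert toy_model.exonic_length - iso.exonic_length == 100
        expected_introns = set(toy_model.introns()) - {(200, 300), (400, 500)} | {(200, 500)}
        assert set(iso.introns()) == expected_introns
        assert (iso.cds_start, iso.cds_end) == (130, 760)

    def test_tag2_shift_trims_target_exon(self, toy_model):
        p = classify_placement(_j(200, 350), toy_model)
        iso = insert_junction(p)
        assert iso.exons == ((100, 200), (350, 400), (500, 560), (700, 800))
        assert toy_model.exonic_length - iso.exonic_length == 50

    def test_tag2_one_bp_shift_rejected(self, toy_model):
        p = classify_placement(_j(200, 301), toy_model)
        with pytest.raises(Rejected) as exc:
            insert_junction(p)
        assert exc.value.reason == "exon-mod"

    def test_tag2_shift_over_max_rejected(self, toy_model):
        wide = TranscriptModel(
            "W", "G", "chrT", "+", ((100, 200), (300, 700)), 120, 690
        )
        p = classify_placement(_j(200, 560), wide)
        assert p.tag == 2
        with pytest.raises(Rejected) as exc:
            insert_junction(p, max_exon_mod=250)
        assert exc.value.reason == "exon-mod"

    def test_tag2_site_in_intron_rejected(self, toy_model):
        p = classify_placement(_j(200, 450), toy_model)  # 450 in intron 2
        with pytest.raises(Rejected) as exc:
            insert_junction(p)
        assert exc.value.reason == "site-in-intron"

    def test_tag3_split_inside_one_exon(self, toy_model):
        p = classify_placement(_j(310, 390), toy_model)
        iso = insert_junction(p)
        assert iso.exons == ((100, 200), (300, 310), (390, 400), (500, 560), (700, 800))
        assert toy_model.exonic_length - iso.exonic_length == 80

    def test_tag3_fifty_bp_intron_rejected(self, toy_model):
        p = classify_placement(_j(310, 360), toy_model)
        with pytest.raises(Rejected) as exc:
            insert_junction(p, min_intron=50)
        assert exc.value.reason == "intron-length"

    def test_tag3_sites_in_different_exons_rejected(self, toy_model):
        p = classify_placement(_j(150, 350), toy_model)
        assert p.tag == 3
        with pytest.raises(Rejected) as exc:
            insert_junction(p)
        assert exc.value.reason == "tag3-multi-exon"

    def test_junction_outside_cds_rejected_as_non_coding(self, toy_model):
        # toy CDS is [130, 760); a split within exon 4 past the stop is UTR
        p = classify_placement(_j(765, 795), toy_model)
        assert p.tag == 3
        with pytest.raises(Rejected) as exc:
            insert_junction(p)
        assert exc.value.reason == "non-coding"

    def test_non_coding_host_rejected(self, toy_model):
        nc = TranscriptModel("NC", "G", "chrT", "+", toy_model.exons)
        p = classify_placement(_j(200, 500), nc)
        with pytest.raises(Rejected) as exc:
            insert_junction(p)
        assert exc.value.reason == "non-coding"

    def test_exons_never_overlap_after_insertion(self, toy_model):
        for j in (_j(200, 500), _j(200, 350), _j(310, 390)):
            iso = insert_junction(classify_placement(j, toy_model))
            for (s1, e1), (s2, e2) in zip(iso.exons, iso.exons[1:]):
                assert e1 < s2
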