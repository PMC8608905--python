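"""Fusion-point refinement, breakpoint linking, fusion-specific
junctions, fragment contexts and double-hop calling."""

import pytest

from isoforge import make_toy_reference
from isoforge.classify import ReferenceIndex
from isoforge.fusion import (
    FusionConfig,
    FusionPoint,
    FusionTranscript,
    build_fusion_transcript,
    call_double_hop,
    classify_fragments,
    fusion_specific_junctions,
    link_breakpoints,
    refine_fusion_point,
)
from isoforge.genome_model import ExonChain
from isoforge.io_formats import AlignedSegment, BreakpointRecord, ReadRecord


def chimeric_read(segments, rid="chim"):
    return ReadRecord(
        rid, "s1", segments[0].chain, is_chimeric=True, segments=list(segments)
    )


@pytest.fixture(scope="module")
def fused_toy():
    toy = make_toy_reference(n_genes=6, isoforms_per_gene=3, seed=11, rearrange=True)
    bp = toy.breakpoints[0]
    _, gA, gB = bp.sv_id.split("_")
    chA = toy.annotation.transcripts[toy.annotation.genes[gA][0]]
    chB = toy.annotation.transcripts[toy.annotation.genes[gB][0]]
    return toy, bp, chA, chB


def perturbed_transcript(chA, chB, offset):
    """A two-segment chimeric read whose raw fusion point is displaced
    from the true spliceable position by ``offset`` (joint shift)."""
    e0 = chA.exons[0]
    sB = chB.exons[-1]
    segA = AlignedSegment(0, e0[1] - e0[0] + offset,
                          ExonChain(chA.chrom, "+", [(e0[0], e0[1] + offset)]), "+")
    segB = AlignedSegment(segA.read_end, segA.read_end + (sB[1] - sB[0]) - offset,
                          ExonChain(chB.chrom, "+", [(sB[0] + offset, sB[1])]), "+")
    return build_fusion_transcript(chimeric_read([segA, segB]))


class TestRefinement:
    def test_planted_junction_recovered_exactly(self, fused_toy):
        toy, bp, chA, chB = fused_toy
        for offset in (-3, 0, 3):
            ft = perturbed_transcript(chA, chB, offset)
            refine_fusion_point(ft, toy.genome)
            pt = ft.fusion_points[0]
            assert pt.is_spliced and pt.motif == "GT-AG"
            assert pt.five_pos == chA.exons[0][1]
            assert pt.three_pos == chB.exons[-1][0]

    def test_no_canonical_candidate_leaves_point_unspliced(self):
        genome = {"c": "A" * 400}
        segA = AlignedSegment(0, 100, ExonChain("c", "+", [(0, 100)]), "+")
        segB = AlignedSegment(100, 200, ExonChain("c", "+", [(200, 300)]), "+")
        ft = build_fusion_transcript(chimeric_read([segA, segB]))
        refine_fusion_point(ft, genome)
        pt = ft.fusion_points[0]
        assert not pt.is_spliced and pt.five_pos == 100 and pt.three_pos == 200

    def test_ambiguous_candidates_leave_point_unchanged(self):
        # two GT...AG placements within the radius
        seq = ["A"] * 400
        for off in (2, 6):
            seq[100 + off] = "G"
            seq[101 + off] = "T"
            seq[198 + off] = "A"
            seq[199 + off] = "G"
        genome = {"c": "".join(seq)}
        segA = AlignedSegment(0, 100, ExonChain("c", "+", [(0, 100)]), "+")
        segB = AlignedSegment(100, 200, ExonChain("c", "+", [(200, 300)]), "+")
        ft = build_fusion_transcript(chimeric_read([segA, segB]))
        refine_fusion_point(ft, genome)
        pt = ft.fusion_points[0]
        assert not pt.is_spliced and pt.five_pos == 100


def make_point(is_spliced, five=("chr1", 50_000), three=("chr2", 80_000)):
    pt = FusionPoint(five[0], five[1], "+", three[0], three[1], "+", is_spliced=is_spliced)
    return FusionTranscript("r", [None, None], [pt])


def sv(posA, posB, chromA="chr1", chromB="chr2", sid="sv1"):
    return BreakpointRecord(chromA, posA, "+", chromB, posB, "+", sid)


class TestLinking:
    def test_spliced_window_inclusive_boundary(self):
        ft = make_point(True)
        link_breakpoints(ft, [sv(50_000 + 99_999, 80_000 + 50)])
        assert ft.fusion_points[0].link is not None
        link_breakpoints(ft, [sv(50_000 + 100_000, 80_000)])
        assert ft.fusion_points[0].link is not None
        link_breakpoints(ft, [sv(50_000 + 100_001, 80_000)])
        assert ft.fusion_points[0].link is None

    def test_exonic_window_inclusive_boundary(self):
        ft = make_point(False)
        link_breakpoints(ft, [sv(50_000 + 99, 80_000 + 99)])
        assert ft.fusion_points[0].link is not None
        link_breakpoints(ft, [sv(50_000 + 101, 80_000)])
        assert ft.fusion_points[0].link is None

    def test_swapped_sv_side_order_links(self):
        ft = make_point(True)
        link_breakpoints(ft, [sv(80_000, 50_000, chromA="chr2", chromB="chr1")])
        assert ft.fusion_points[0].link is not None

    def test_nearest_sv_wins(self):
        ft = make_point(True)
        near = sv(50_010, 80_010, sid="near")
        far = sv(50_500, 80_500, sid="far")
        link_breakpoints(ft, [far, near])
        assert ft.fusion_points[0].link.sv_id == "near"
        assert ft.fusion_points[0].link_distance == 20.0


class TestFusionSpecificJunctions:
    def test_reference_and_cohort_junctions_excluded(self, fused_toy):
        toy, bp, chA, chB = fused_toy
        idx = ReferenceIndex.from_annotation(toy.annotation)
        # segment B carries an annotated junction of gene B
        segA = AlignedSegment(0, 100, ExonChain(chA.chrom, "+", [chA.exons[0]]), "+")
        segB = AlignedSegment(100, 400, ExonChain(chB.chrom, "+", list(chB.exons[-2:])), "+")
        ft = build_fusion_transcript(chimeric_read([segA, segB]))
        found, keep = fusion_specific_junctions(ft, idx, set(), toy.genome)
        assert found == [] and keep

    def test_novel_canonical_junction_reported_3prime(self, fused_toy):
        toy, bp, chA, chB = fused_toy
        idx = ReferenceIndex.from_annotation(toy.annotation)
        # novel junction on segment B: skip an exon boundary by shifting
        # the inner edge into the intron (keeps GT donor at annotated pos)
        # exon-skip on another gene's transcript: its skip junction is
        # canonical (annotated donor + acceptor) but unannotated as a pair
        skip = None
        for c in toy.annotation.transcripts.values():
            if c.strand != "+" or len(c.exons) < 4:
                continue
            for k in range(1, len(c.exons) - 1):
                cand = ExonChain(c.chrom, "+", [e for i, e in enumerate(c.exons) if i != k])
                novel_j = [
                    j for j in cand.junctions
                    if (j.chrom, j.strand, j.donor_pos, j.acceptor_pos) not in idx.junction_set
                ]
                if novel_j:
                    skip = cand
                    break
            if skip is not None:
                break
        assert skip is not None  # some exon skip must be unannotated
        segA = AlignedSegment(0, 100, ExonChain(chA.chrom, "+", [chA.exons[0]]), "+")
        segB = AlignedSegment(100, 500, skip, "+")
        ft = build_fusion_transcript(chimeric_read([segA, segB]))
        found, keep = fusion_specific_junctions(ft, idx, set(), toy.genome)
        assert keep
        assert [(pos) for _, m, pos in found] == ["3prime"] * len(found)
        assert all(m == "GT-AG" for _, m, _ in found)
        # the same junction present in the cohort set is no longer specific
        cohort = {(j.chrom, j.strand, j.donor_pos, j.acceptor_pos) for j in skip.junctions}
        found2, _ = fusion_specific_junctions(ft, idx, cohort, toy.genome)
        assert found2 == []

    def test_noncanonical_novel_junction_discards_read(self, fused_toy):
        toy, bp, chA, chB = fused_toy
        idx = ReferenceIndex.from_annotation(toy.annotation)
        t = next(c for c in toy.annotation.transcripts.values() if c.strand == "+" and len(c.exons) >= 2)
        ex = list(t.exons)
        ex[0] = (ex[0][0], ex[0][1] - 5)  # novel donor, almost surely non-GT
        shifted = ExonChain(t.chrom, "+", ex)
        from isoforge.classify import junction_motif

        j0 = shifted.junctions[0]
        if junction_motif(toy.genome, j0) != "noncanonical":
            pytest.skip("random sequence happened to be canonical at the shift")
        segA = AlignedSegment(0, 100, ExonChain(chA.chrom, "+", [chA.exons[0]]), "+")
        segB = AlignedSegment(100, 500, shifted, "+")
        ft = build_fusion_transcript(chimeric_read([segA, segB]))
        found, keep = fusion_specific_junctions(ft, idx, set(), toy.genome)
        assert not keep


class TestFragmentContexts:
    def test_intron_fragment_is_non_genic(self, fused_toy):
        toy, bp, chA, chB = fused_toy
        idx = ReferenceIndex.from_annotation(toy.annotation)
        intron = (chA.exons[0][1] + 10, chA.exons[1][0] - 10)
        segA = AlignedSegment(0, intron[1] - intron[0],
                              ExonChain(chA.chrom, chA.strand, [intron]), chA.strand)
        segB = AlignedSegment(segA.read_end, segA.read_end + 100,
                              ExonChain(chB.chrom, "+", [chB.exons[-1]]), "+")
        ft = build_fusion_transcript(chimeric_read([segA, segB]))
        seg_info, point_info = classify_fragments(ft, idx)
        assert seg_info[0]["region"] == "genic_intron"
        assert point_info[0][0] == "non_genic"

    def test_constitutive_vs_alternative_exon_break(self):
        # toy gene: 3 transcripts; exon (100,200) in all, exon (300,400) in 1
        from isoforge.io_formats import ReferenceAnnotation

        e_all, e_alt, e_last = (100, 200), (300, 400), (500, 600)
        t1 = ExonChain("c", "+", [e_all, e_alt, e_last])
        t2 = ExonChain("c", "+", [e_all, e_last])
        t3 = ExonChain("c", "+", [e_all, e_last])
        ann = ReferenceAnnotation(
            {"t1": t1, "t2": t2, "t3": t3},
            {"t1": "g", "t2": "g", "t3": "g"},
            {"g": ["t1", "t2", "t3"]},
        )
        idx = ReferenceIndex.from_annotation(ann)
        far = ExonChain("d", "+", [(0, 100)])

        def context_of(break_exon, pos_in_exon):
            seg5 = AlignedSegment(
                0, 50, ExonChain("c", "+", [(break_exon[0], break_exon[0] + pos_in_exon)]), "+"
            )
            seg3 = AlignedSegment(50, 150, far, "+")
            ft = build_fusion_transcript(chimeric_read([seg5, seg3]))
            _, points = classify_fragments(ft, idx)
            return points[0][0]

        assert context_of(e_all, 50) == "cons_exonic"
        assert context_of(e_alt, 50) == "alt_exonic"

    def test_intronic_break_in_genic_fragment(self):
        from isoforge.io_formats import ReferenceAnnotation

        t1 = ExonChain("c", "+", [(100, 200), (300, 400)])
        ann = ReferenceAnnotation({"t1": t1}, {"t1": "g"}, {"g": ["t1"]})
        idx = ReferenceIndex.from_annotation(ann)
        # fragment covers exon 1 and runs into the intron -> genic, break intronic
        seg5 = AlignedSegment(0, 150, ExonChain("c", "+", [(100, 250)]), "+")
        seg3 = AlignedSegment(150, 250, ExonChain("d", "+", [(0, 100)]), "+")
        ft = build_fusion_transcript(chimeric_read([seg5, seg3]))
        seg_info, points = classify_fragments(ft, idx)
        assert seg_info[0]["region"] == "genic"
        assert points[0][0] == "intronic_downstream"


class TestDoubleHop:
    def three_piece(self, rid="chim"):
        segs = [
            AlignedSegment(0, 100, ExonChain("chr1", "+", [(0, 100)]), "+"),
            AlignedSegment(100, 200, ExonChain("chr2", "+", [(5000, 5100)]), "+"),
            AlignedSegment(200, 300, ExonChain("chr3", "+", [(9000, 9100)]), "+"),
        ]
        return build_fusion_transcript(chimeric_read(segs, rid=rid))

    def test_statuses(self):
        both = self.three_piece("both")
        link_breakpoints(both, [sv(100, 5000, "chr1", "chr2", "a"),
                                sv(5100, 9000, "chr2", "chr3", "b")])
        one = self.three_piece("one")
        link_breakpoints(one, [sv(100, 5000, "chr1", "chr2", "a")])
        none = self.three_piece("none")
        link_breakpoints(none, [])
        two_seg = build_fusion_transcript(chimeric_read([
            AlignedSegment(0, 100, ExonChain("chr1", "+", [(0, 100)]), "+"),
            AlignedSegment(100, 200, ExonChain("chr2", "+", [(5000, 5100)]), "+"),
        ], rid="two"))
        report = call_double_hop([both, one, none, two_seg])
        assert report["both"] == "both_linked" and report["two"] == "not_applicable"
        statuses = [ft.double_hop_status for ft in (both, one, none, two_seg)]
        assert statuses == [
            "both_linked", "one_linked_one_unlinked", "unlinked", "not_applicable",
        ]
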