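"""Chimeric-read fusion-transcript analysis.

A chimeric long read aligns in >= 2 segments to distinct genomic
regions; each boundary between consecutive segments (in read order,
i.e. transcript 5'->3') is a fusion point.  Because long reads carry
sequencing error, the raw fusion point has a few bp of uncertainty: if
exactly one offset within that radius places a canonical donor-acceptor
motif pair (GT-AG / GC-AG / AT-AC) across the break, that position is
adopted and the point is called spliced.  Points are then linked to WGS
structural-variant breakpoints within 100,000 bp (spliced points, which
may sit an intron away from the genomic break) or 100 bp (exonic
points).  Three-segment reads whose two fusion points are both linked
are confirmed double-hop fusion transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import ReferenceIndex, revcomp, junction_motif
from .genome_model import ExonChain, SpliceJunction
from .io_formats import BreakpointRecord, ReadRecord

__all__ = [
    "FusionConfig",
    "FusionPoint",
    "FusionTranscript",
    "build_fusion_transcript",
    "refine_fusion_point",
    "link_breakpoints",
    "fusion_specific_junctions",
    "classify_fragments",
    "call_double_hop",
]

_ALLOWED_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}


@dataclass
class FusionConfig:
    spliced_window: int = 100_000
    exonic_window: int = 100
    refine_radius: int = 10

    def __post_init__(self) -> None:
        if self.spliced_window <= 0 or self.exonic_window <= 0:
            raise ValueError("windows must be > 0")


@dataclass
class FusionPoint:
    """Boundary between consecutive segments of a chimeric read.

    ``five_pos`` is the genomic coordinate of the transcript-3' edge of
    the upstream segment (half-open boundary); ``three_pos`` the
    transcript-5' edge of the downstream segment."""

    five_chrom: str
    five_pos: int
    five_strand: str
    three_chrom: str
    three_pos: int
    three_strand: str
    is_spliced: bool = False
    motif: str | None = None
    link: BreakpointRecord | None = None
    link_distance: float | None = None


@dataclass
class FusionTranscript:
    read_id: str
    segments: list  # AlignedSegment, ordered by read coordinate
    fusion_points: list = field(default_factory=list)
    double_hop_status: str = "not_applicable"

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def build_fusion_transcript(read: ReadRecord) -> FusionTranscript:
    """Derive the fusion points of a chimeric read from its ordered
    segments."""
    if not read.is_chimeric or len(read.segments) < 2:
        raise ValueError("read is not chimeric")
    if len(read.segments) > 3:
        raise ValueError("only 2- and 3-segment fusion transcripts are handled")
    points = []
    for seg5, seg3 in zip(read.segments, read.segments[1:]):
        c5 = seg5.chain
        c3 = seg3.chain
        five_pos = c5.end if c5.strand == "+" else c5.start
        three_pos = c3.start if c3.strand == "+" else c3.end
        points.append(
            FusionPoint(c5.chrom, five_pos, c5.strand, c3.chrom, three_pos, c3.strand)
        )
    return FusionTranscript(read.read_id, list(read.segments), points)


def _donor_at(genome, chrom, strand, pos):
    """Two intronic bases transcript-downstream of a 5'-side break at
    half-open boundary ``pos``."""
    seq = genome[chrom]
    if strand == "+":
        if pos + 2 > len(seq):
            return None
        return str(seq[pos : pos + 2]).upper()
    if pos - 2 < 0:
        return None
    return revcomp(str(seq[pos - 2 : pos]).upper())


def _acceptor_at(genome, chrom, strand, pos):
    """Two intronic bases transcript-upstream of a 3'-side break."""
    seq = genome[chrom]
    if strand == "+":
        if pos - 2 < 0:
            return None
        return str(seq[pos - 2 : pos]).upper()
    if pos + 2 > len(seq):
        return None
    return revcomp(str(seq[pos : pos + 2]).upper())


def refine_fusion_point(ft: FusionTranscript, genome, cfg: FusionConfig | None = None) -> None:
    """Scan joint offsets delta in [-radius, +radius] applied to both
    sides of each fusion point (moving the break along the read, so the
    transcript sequence length is preserved).  If exactly one offset
    yields an allowed donor-acceptor motif pair, adopt it and mark the
    point spliced; with zero or several candidates the point is left at
    the raw position, unspliced."""
    cfg = cfg or FusionConfig()
    for pt in ft.fusion_points:
        candidates = []
        for delta in range(-cfg.refine_radius, cfg.refine_radius + 1):
            p5 = pt.five_pos + (delta if pt.five_strand == "+" else -delta)
            p3 = pt.three_pos + (delta if pt.three_strand == "+" else -delta)
            donor = _donor_at(genome, pt.five_chrom, pt.five_strand, p5)
            acceptor = _acceptor_at(genome, pt.three_chrom, pt.three_strand, p3)
            if donor is None or acceptor is None:
                continue
            if (donor, acceptor) in _ALLOWED_PAIRS:
                candidates.append((delta, p5, p3, f"{donor}-{acceptor}"))
        if len(candidates) == 1:
            _, p5, p3, motif = candidates[0]
            pt.five_pos, pt.three_pos = p5, p3
            pt.is_spliced = True
            pt.motif = motif
        else:
            pt.is_spliced = False
            pt.motif = None


def _side_distance(chrom1, pos1, chrom2, pos2):
    if chrom1 != chrom2:
        return None
    return abs(pos1 - pos2)


def link_breakpoints(ft: FusionTranscript, svs, cfg: FusionConfig | None = None) -> None:
    """Link each fusion point to the nearest structural variant whose
    two breakpoint sides both fall within the class window (inclusive):
    spliced points use ``spliced_window``, exonic (unspliced) points
    ``exonic_window``.  Ties resolve to minimal summed distance."""
    cfg = cfg or FusionConfig()
    for pt in ft.fusion_points:
        w = cfg.spliced_window if pt.is_spliced else cfg.exonic_window
        best = None
        for sv in svs:
            for (ca, pa), (cb, pb) in (
                ((sv.chromA, sv.posA), (sv.chromB, sv.posB)),
                ((sv.chromB, sv.posB), (sv.chromA, sv.posA)),
            ):
                d5 = _side_distance(pt.five_chrom, pt.five_pos, ca, pa)
                d3 = _side_distance(pt.three_chrom, pt.three_pos, cb, pb)
                if d5 is None or d3 is None or d5 > w or d3 > w:
                    continue
                total = d5 + d3
                if best is None or total < best[0]:
                    best = (total, sv)
        if best is not None:
            pt.link = best[1]
            pt.link_distance = float(best[0])
        else:
            pt.link = None
            pt.link_distance = None


def is_confirmed(ft: FusionTranscript) -> bool:
    """A fusion transcript is confirmed when every fusion point has a
    linked genomic breakpoint."""
    return all(pt.link is not None for pt in ft.fusion_points)


def fusion_specific_junctions(
    ft: FusionTranscript,
    ref: ReferenceIndex,
    cohort_junctions: set,
    genome,
):
    """Intra-segment splice junctions absent from both the reference
    annotation and the non-chimeric cohort transcriptome.

    Returns (junctions, keep): ``junctions`` is a list of
    (SpliceJunction, motif, position) where position is '5prime' or
    '3prime' of the (first) fusion point; ``keep`` is False when the
    read carries a fusion-specific junction with a non-canonical motif
    (such reads are discarded as artifacts)."""
    found = []
    keep = True
    for si, seg in enumerate(ft.segments):
        for j in seg.chain.junctions:
            jkey = (j.chrom, j.strand, j.donor_pos, j.acceptor_pos)
            if jkey in ref.junction_set or jkey in cohort_junctions:
                continue
            motif = junction_motif(genome, j)
            position = "5prime" if si == 0 else "3prime"
            found.append((j, motif, position))
            if motif == "noncanonical":
                keep = False
    return found, keep


def classify_fragments(ft: FusionTranscript, ref: ReferenceIndex):
    """Per-segment genomic context and per-fusion-point-side context.

    Segment context: genic / genic_intron / antisense / intergenic (by
    same-strand exon overlap, intron containment, opposite-strand gene
    overlap).  Fusion-point side context: non_genic when the fragment is
    non-genic; cons_exonic when the break falls inside an exon present
    in every transcript of the gene; alt_exonic in an exon of only some
    transcripts; intronic_downstream otherwise."""
    seg_info = []
    for seg in ft.segments:
        ch = seg.chain
        genes = ref.exon_overlap_genes(ch)
        if genes:
            region = "genic"
        elif ref.contained_in_intron(ch):
            region = "genic_intron"
        else:
            overlapping = ref.overlapping_genes(ch)
            if overlapping and all(st != ch.strand for _, st in overlapping):
                region = "antisense"
            elif overlapping:
                region = "genic"
            else:
                region = "intergenic"
        seg_info.append({"region": region, "n_exons": ch.n_exons, "genes": sorted(genes)})

    point_info = []
    for i, pt in enumerate(ft.fusion_points):
        sides = []
        for (chrom, pos, strand), seg in (
            ((pt.five_chrom, pt.five_pos, pt.five_strand), seg_info[i]),
            ((pt.three_chrom, pt.three_pos, pt.three_strand), seg_info[i + 1]),
        ):
            if seg["region"] != "genic":
                sides.append("non_genic")
                continue
            # base just inside the fragment at the break
            base = pos - 1 if (strand == "+") == (seg is seg_info[i]) else pos
            ctx = "intronic_downstream"
            for gid in seg["genes"]:
                exons = ref.gene_exons.get(gid, set())
                hit = [(s, e) for s, e in exons if s <= base < e]
                if hit:
                    gene_tids = [t for t, g in ref.transcript_gene.items() if g == gid]
                    constitutive = all(
                        any(s2 <= base < e2 for s2, e2 in ref.transcripts[t].exons)
                        for t in gene_tids
                    )
                    ctx = "cons_exonic" if constitutive else "alt_exonic"
                    break
            sides.append(ctx)
        point_info.append(tuple(sides))
    return seg_info, point_info


def call_double_hop(fts) -> dict:
    """Label three-segment fusion transcripts by breakpoint support:
    both points linked -> confirmed double-hop; exactly one linked ->
    candidate for external breakpoint search; none -> rejected.
    Two-segment reads are not applicable."""
    report = {}
    for ft in fts:
        if ft.n_segments != 3:
            ft.double_hop_status = "not_applicable"
        else:
            linked = sum(1 for pt in ft.fusion_points if pt.link is not None)
            ft.double_hop_status = {
                2: "both_linked",
                1: "one_linked_one_unlinked",
                0: "unlinked",
            }[linked]
        report[ft.read_id] = ft.double_hop_status
    return report
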