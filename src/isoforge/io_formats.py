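"""Readers and writers for the external formats the pipeline touches.

GTF follows the GENCODE dialect (1-based inclusive on disk; converted to
the package's 0-based half-open coordinates on read).  Alignments come in
as SAM/BAM (pysam) or PAF with a ``cg:Z`` CIGAR tag; both are reduced to
exon chains by the same CIGAR interpreter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import ExonChain

__all__ = [
    "ReadRecord",
    "AlignedSegment",
    "AlignmentFilterConfig",
    "BreakpointRecord",
    "ReferenceAnnotation",
    "read_gtf",
    "write_gtf",
    "write_annotation_gtf",
    "read_alignments",
    "read_breakpoints",
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "write_fasta",
    "read_sample_sheet",
    "cigar_to_exons",
]


@dataclass
class AlignedSegment:
    """One aligned piece of a read: read-coordinate interval (on the
    original read orientation), the genomic exon-chain fragment it maps
    to, and the alignment strand."""

    read_start: int
    read_end: int
    chain: ExonChain
    strand: str
    mapq: int = 255


@dataclass
class ReadRecord:
    """A mapped long read.  Non-chimeric reads have exactly one segment
    whose chain is also exposed as ``chain``; chimeric reads carry >= 2
    segments ordered by read coordinate (i.e. transcript 5'->3')."""

    read_id: str
    sample_id: str
    chain: ExonChain
    fl_count: int = 1
    mapq: int = 255
    is_chimeric: bool = False
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fl_count < 1:
            raise ValueError("fl_count must be >= 1")
        if not self.segments:
            self.segments = [
                AlignedSegment(0, self.chain.exonic_length(), self.chain, self.chain.strand, self.mapq)
            ]
        if not self.is_chimeric and len(self.segments) != 1:
            raise ValueError("non-chimeric read must have exactly one segment")


@dataclass
class AlignmentFilterConfig:
    """Only alignments with mapping quality strictly greater than
    ``min_mapq`` are kept (default 50).  Alignment gaps shorter than
    ``min_intron`` are treated as deletions and merged into exons."""

    min_mapq: int = 50
    min_intron: int = 20

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class BreakpointRecord:
    """A genomic structural-variant breakpoint pair (e.g. from WGS)."""

    chromA: str
    posA: int
    orientA: str
    chromB: str
    posB: int
    orientB: str
    sv_id: str

    def __post_init__(self) -> None:
        if self.posA < 0 or self.posB < 0:
            raise ValueError("breakpoint positions must be >= 0")


@dataclass
class ReferenceAnnotation:
    """Transcript models grouped by gene."""

    transcripts: dict  # transcript_id -> ExonChain
    transcript_gene: dict  # transcript_id -> gene_id
    genes: dict  # gene_id -> list of transcript ids

    def gene_of(self, tid: str) -> str:
        return self.transcript_gene[tid]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str) -> ReferenceAnnotation:
    """Parse a GENCODE-style GTF into transcript exon chains grouped by
    gene.  Exons out of order in the file are sorted; a malformed feature
    line raises a parse error naming the line."""
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # re-raise with file context
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc

    exons_by_tx: dict = {}
    meta: dict = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        gid = ex.attributes.get("gene_id", [tid])[0]
        if ex.end < ex.start:
            raise ValueError(f"GTF {path}: exon with end < start in transcript {tid}")
        exons_by_tx.setdefault(tid, []).append((ex.start - 1, ex.end))
        meta[tid] = (ex.seqid, ex.strand, gid)

    transcripts, transcript_gene, genes = {}, {}, {}
    for tid, exons in exons_by_tx.items():
        chrom, strand, gid = meta[tid]
        exons = sorted(set(exons))
        transcripts[tid] = ExonChain(chrom, strand, exons)
        transcript_gene[tid] = gid
        genes.setdefault(gid, []).append(tid)
    return ReferenceAnnotation(transcripts, transcript_gene, genes)


def write_annotation_gtf(records, path: str, source: str = "isoforge") -> None:
    """Write (gene_id, transcript_id, ExonChain) triples as GTF."""
    with open(path, "w") as fh:
        fh.write("##description: isoforge transcript models\n")
        for gid, tid, chain in records:
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            fh.write(
                f"{chain.chrom}\t{source}\ttranscript\t{chain.start + 1}\t{chain.end}\t.\t"
                f"{chain.strand}\t.\t{attrs}\n"
            )
            for s, e in chain.exons:
                fh.write(
                    f"{chain.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{chain.strand}\t.\t{attrs}\n"
                )


def write_gtf(isoforms, path: str) -> None:
    """Write collapsed isoforms as GTF with PB.<gene>.<iso>-style ids."""
    write_annotation_gtf(
        ((iso.gene_group_id, iso.isoform_id, iso.chain) for iso in isoforms), path
    )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

_REF_OPS = {0, 2, 3, 7, 8}  # M D N = X consume reference
_QRY_OPS = {0, 1, 4, 7, 8}  # M I S = X consume query


def cigar_to_exons(cigartuples, ref_start: int, min_intron: int = 20):
    """Convert CIGAR operations into exon blocks.

    Reference gaps (N, or D of length >= ``min_intron``) open a new exon;
    shorter deletions are bridged.  Returns (exons, query_start,
    query_end, query_length) in read coordinates of the stored (aligned)
    orientation.
    """
    exons = []
    ref = ref_start
    q = 0
    q_end = 0
    q_start = None
    exon_start = ref
    open_exon = False
    for op, ln in cigartuples:
        if op in (4, 5):  # soft/hard clip
            if op == 4:
                q += ln
            continue
        if op in (0, 7, 8):  # aligned block
            if q_start is None:
                q_start = q
            if not open_exon:
                exon_start = ref
                open_exon = True
            ref += ln
            q += ln
            q_end = q
        elif op == 1:  # insertion
            q += ln
            q_end = q
        elif op in (2, 3):  # deletion / intron
            is_intron = op == 3 or ln >= min_intron
            if is_intron and open_exon:
                exons.append((exon_start, ref))
                open_exon = False
            ref += ln
    if open_exon:
        exons.append((exon_start, ref))
    return exons, (q_start or 0), q_end, q


def _segment_from_pysam(aln, min_intron: int) -> AlignedSegment:
    exons, qs, qe, _ = cigar_to_exons(aln.cigartuples, aln.reference_start, min_intron)
    strand = "-" if aln.is_reverse else "+"
    chain = ExonChain(aln.reference_name, strand, exons)
    # read coordinates on the original (sequencer) orientation
    read_len = aln.infer_read_length()
    qs_full = qs + (aln.cigartuples[0][1] if aln.cigartuples[0][0] == 5 else 0)
    qe_full = qe + (aln.cigartuples[0][1] if aln.cigartuples[0][0] == 5 else 0)
    if aln.is_reverse:
        qs_full, qe_full = read_len - qe_full, read_len - qs_full
    return AlignedSegment(qs_full, qe_full, chain, strand, aln.mapping_quality)


def read_alignments(path, cfg: AlignmentFilterConfig | None = None,
                    sample_id: str = "sample", fl_counts: dict | None = None) -> list:
    """Read spliced long-read alignments (SAM/BAM or PAF with cg tag)
    into ReadRecords.

    Alignments with mapq <= cfg.min_mapq are dropped (strictly greater
    required).  Reads left with >= 2 primary/supplementary segments are
    flagged chimeric, segments ordered by read coordinate.  ``fl_counts``
    optionally maps read_id -> full-length count (default 1).
    """
    cfg = cfg or AlignmentFilterConfig()
    fl_counts = fl_counts or {}
    path = str(path)
    segs_by_read: dict = {}
    if path.endswith(".paf"):
        for seg_id, seg in _iter_paf_segments(path, cfg):
            segs_by_read.setdefault(seg_id, []).append(seg)
    else:
        mode = "rb" if path.endswith(".bam") else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary:
                    continue
                if aln.mapping_quality <= cfg.min_mapq:
                    continue
                segs_by_read.setdefault(aln.query_name, []).append(
                    _segment_from_pysam(aln, cfg.min_intron)
                )
    records = []
    for rid in sorted(segs_by_read):
        segs = sorted(segs_by_read[rid], key=lambda s: (s.read_start, s.read_end))
        fl = int(fl_counts.get(rid, 1))
        chimeric = len(segs) > 1
        rec = ReadRecord(
            read_id=rid,
            sample_id=sample_id,
            chain=segs[0].chain,
            fl_count=fl,
            mapq=min(s.mapq for s in segs),
            is_chimeric=chimeric,
            segments=segs,
        )
        records.append(rec)
    return records


def _iter_paf_segments(path: str, cfg: AlignmentFilterConfig):
    import re

    cig_re = re.compile(r"(\d+)([MIDNSHP=X])")
    opcode = {c: i for i, c in enumerate("MIDNSHP=X")}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"PAF {path}: line {ln}: fewer than 12 columns")
            qname, qstart, qend = f[0], int(f[2]), int(f[3])
            strand, tname, tstart = f[4], f[5], int(f[7])
            mapq = int(f[11])
            if mapq <= cfg.min_mapq:
                continue
            cg = next((c[5:] for c in f[12:] if c.startswith("cg:Z:")), None)
            if cg:
                tuples = [(opcode[m[2]], int(m[1])) for m in cig_re.finditer(cg)]
                exons, _, _, _ = cigar_to_exons(tuples, tstart, cfg.min_intron)
            else:
                exons = [(tstart, int(f[8]))]
            chain = ExonChain(tname, strand, exons)
            yield qname, AlignedSegment(qstart, qend, chain, strand, mapq)


# ---------------------------------------------------------------------------
# Simple tabular / sequence formats
# ---------------------------------------------------------------------------

def read_breakpoints(path) -> list:
    """Read a BEDPE-like TSV (header: chromA posA orientA chromB posB
    orientB sv_id) of genomic breakpoint pairs."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        required = ["chromA", "posA", "orientA", "chromB", "posB", "orientB", "sv_id"]
        missing = [c for c in required if c not in idx]
        if missing:
            raise ValueError(f"breakpoint file {path} missing columns: {missing}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                BreakpointRecord(
                    f[idx["chromA"]], int(f[idx["posA"]]), f[idx["orientA"]],
                    f[idx["chromB"]], int(f[idx["posB"]]), f[idx["orientB"]],
                    f[idx["sv_id"]],
                )
            )
    return out


def write_breakpoints(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("chromA\tposA\torientA\tchromB\tposB\torientB\tsv_id\n")
        for r in records:
            fh.write(f"{r.chromA}\t{r.posA}\t{r.orientA}\t{r.chromB}\t{r.posB}\t{r.orientB}\t{r.sv_id}\n")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        str(path),
        "fasta",
    )


def read_fastq(path) -> list:
    """Return (id, sequence, quality-string) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), quals))
    return out


def write_fastq(reads, path) -> None:
    """Write (id, sequence, quality-string) triples as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_sample_sheet(path) -> dict:
    """TSV with header (sample_id, group) -> ordered sample -> group map.
    Duplicate sample ids are an error."""
    mapping: dict = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "group"]:
            raise ValueError(f"sample sheet {path}: expected header 'sample_id\\tgroup'")
        for line in fh:
            if not line.strip():
                continue
            sid, group = line.rstrip("\n").split("\t")[:2]
            if sid in mapping:
                raise ValueError(f"sample sheet {path}: duplicate sample_id {sid!r}")
            mapping[sid] = group
    return mapping
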