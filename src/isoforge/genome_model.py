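"""Core genomic coordinate types and junction-chain algebra.

Every position in the package is 0-based, half-open on the forward
genomic strand; transcript orientation (5'->3') is derived from the
strand at the point of use.  Multi-exon isoform identity is carried
entirely by the ordered splice-junction chain: exon end coordinates
(TSS/TTS) are deliberately excluded from the merge key because long-read
5' degradation makes them unreliable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "SpliceJunction",
    "ExonChain",
    "junction_key",
    "is_five_prime_truncation",
    "chains_overlap",
]

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class SpliceJunction:
    """An intron: donor_pos is the first intronic base (genomic left edge),
    acceptor_pos the half-open genomic right edge.  Orientation relative to
    the transcript is carried by ``strand``: on '-' the transcript-level
    donor site sits at the genomic right edge.
    """

    chrom: str
    strand: str
    donor_pos: int
    acceptor_pos: int

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.donor_pos < self.acceptor_pos:
            raise ValueError("require donor_pos < acceptor_pos (genomic intron)")

    @property
    def intron(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.donor_pos, self.acceptor_pos, self.strand)


_mono_counter = itertools.count()


@dataclass(eq=True)
class ExonChain:
    """Ordered exon structure of one transcript or read alignment.

    ``exons`` are in genomic order, non-overlapping, separated by >= 1 nt.
    Junctions are derived; a mono-exon chain has none.
    """

    chrom: str
    strand: str
    exons: tuple

    def __init__(self, chrom: str, strand: str, exons) -> None:
        self.chrom = chrom
        self.strand = strand
        self.exons = tuple(
            (e.start, e.end) if isinstance(e, GenomicInterval) else (int(e[0]), int(e[1]))
            for e in exons
        )
        if not self.exons:
            raise ValueError("chain needs >= 1 exon")
        if strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        prev_end = None
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"exon [{s}, {e}) is empty or inverted")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons must be sorted with gaps >= 1 nt")
            prev_end = e

    # --- derived geometry -------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_mono(self) -> bool:
        return len(self.exons) == 1

    @property
    def junctions(self) -> tuple:
        """Genomically ordered introns."""
        return tuple(
            SpliceJunction(self.chrom, self.strand, self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcript 5' end (half-open aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def with_ends(self, new_start: int, new_end: int) -> "ExonChain":
        """Return a copy whose first/last exon boundaries are moved outward
        (or inward, if still valid) to the given genomic span ends."""
        exons = list(self.exons)
        exons[0] = (new_start, exons[0][1])
        exons[-1] = (exons[-1][0], new_end)
        return ExonChain(self.chrom, self.strand, exons)


def junction_key(chain: ExonChain) -> str:
    """Merge key of a chain.

    Multi-exon chains: chromosome, strand and the ordered intron
    coordinates — end coordinates are ignored, so reads differing only in
    TSS/TTS collide (and merge).  Mono-exon chains receive a sentinel key
    unique to the chain object, so key-based grouping can never merge
    them; mono-exon merging goes through the overlap rule instead.
    """
    if chain.is_mono:
        tok = getattr(chain, "_mono_token", None)
        if tok is None:
            tok = next(_mono_counter)
            chain._mono_token = tok
        return f"mono::{chain.chrom}{chain.strand}:{chain.start}-{chain.end}::{tok}"
    introns = ";".join(f"{s[1]}-{e[0]}" for s, e in zip(chain.exons, chain.exons[1:]))
    return f"{chain.chrom}{chain.strand}:{introns}"


def is_five_prime_truncation(short: ExonChain, long: ExonChain) -> bool:
    """True iff ``short`` looks like a 5'-degraded fragment of ``long``.

    Requires: both multi-exon, same chromosome/strand; short's junctions
    equal a contiguous 3'-terminal run of long's junctions in transcript
    orientation (genomically right-most on '+', left-most on '-'); short
    has strictly fewer junctions; and short's genomic span is contained in
    long's (a read extending 5' past the long isoform is not a fragment
    of it).
    """
    if short.is_mono or long.is_mono:
        raise ValueError("truncation test is defined for multi-exon chains only")
    if short.chrom != long.chrom or short.strand != long.strand:
        return False
    sj, lj = short.junctions, long.junctions
    k = len(sj)
    if k >= len(lj):
        return False
    if short.strand == "+":
        if lj[-k:] != sj:
            return False
    else:
        if lj[:k] != sj:
            return False
    return long.start <= short.start and short.end <= long.end


def chains_overlap(a: ExonChain, b: ExonChain, same_strand: bool = True) -> bool:
    """True iff the genomic spans of the two chains intersect (half-open),
    on the same chromosome, optionally requiring equal strands."""
    if a.chrom != b.chrom:
        return False
    if same_strand and a.strand != b.strand:
        return False
    return a.start < b.end and b.start < a.end


def exons_overlap(a: ExonChain, b: ExonChain) -> bool:
    """True iff some exon of ``a`` intersects some exon of ``b`` (same
    chromosome and strand required).  Used for gene grouping."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    i = j = 0
    ea, eb = a.exons, b.exons
    while i < len(ea) and j < len(eb):
        s1, e1 = ea[i]
        s2, e2 = eb[j]
        if s1 < e2 and s2 < e1:
            return True
        if e1 <= e2:
            i += 1
        else:
            j += 1
    return False
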