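"""SQANTI-style categorization of isoforms against a reference
annotation, splice-junction motif classes, and rule-based artifact
labels.

Multi-exon queries run down a fixed ladder:

FSM (junction chain equals a reference transcript's full chain)
 > fusion (same-strand exonic overlap with >= 2 reference genes, with a
   junction bridging between gene spans)
 > ISM (chain is a contiguous subchain of a reference transcript)
 > NIC (all donors and acceptors annotated, but the chain itself is not)
 > NNIC (at least one unannotated donor or acceptor).

Mono-exon queries fall through to genic / genic_intron / antisense /
intergenic based on same-strand exon overlap, intron containment, or
opposite-strand gene overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .genome_model import ExonChain, SpliceJunction

__all__ = [
    "ReferenceIndex",
    "CATEGORIES",
    "classify_isoform",
    "junction_motif",
    "artifact_labels",
    "revcomp",
]

CATEGORIES = (
    "FSM", "ISM", "NIC", "NNIC", "genic", "genic_intron", "antisense", "intergenic", "fusion",
)

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _donor_acceptor(j: SpliceJunction):
    """Strand-aware (chrom, strand, pos) site ids for the junction's
    donor (transcript 5' side) and acceptor (3' side)."""
    if j.strand == "+":
        return (j.chrom, "+", j.donor_pos), (j.chrom, "+", j.acceptor_pos)
    return (j.chrom, "-", j.acceptor_pos), (j.chrom, "-", j.donor_pos)


@dataclass
class ReferenceIndex:
    """Annotation-derived lookup structures for classification."""

    transcripts: dict  # transcript_id -> ExonChain
    transcript_gene: dict
    junction_chains: set = field(default_factory=set)  # full chains as tuples
    junction_set: set = field(default_factory=set)
    donor_set: set = field(default_factory=set)
    acceptor_set: set = field(default_factory=set)
    gene_spans: dict = field(default_factory=dict)  # gene -> (chrom, start, end, strand)
    gene_exons: dict = field(default_factory=dict)  # gene -> set of (start, end)
    _exon_trees: dict = field(default_factory=dict)  # (chrom, strand) -> IntervalTree of gene ids
    _intron_trees: dict = field(default_factory=dict)
    _gene_trees: dict = field(default_factory=dict)

    @classmethod
    def from_annotation(cls, ann) -> "ReferenceIndex":
        idx = cls(transcripts=dict(ann.transcripts), transcript_gene=dict(ann.transcript_gene))
        for tid, chain in ann.transcripts.items():
            gid = ann.transcript_gene[tid]
            idx.junction_chains.add(_chain_tuple(chain))
            for j in chain.junctions:
                idx.junction_set.add((j.chrom, j.strand, j.donor_pos, j.acceptor_pos))
                d, a = _donor_acceptor(j)
                idx.donor_set.add(d)
                idx.acceptor_set.add(a)
                idx._intron_trees.setdefault((j.chrom, j.strand), IntervalTree()).addi(
                    j.donor_pos, j.acceptor_pos, gid
                )
            for s, e in chain.exons:
                idx.gene_exons.setdefault(gid, set()).add((s, e))
                idx._exon_trees.setdefault((chain.chrom, chain.strand), IntervalTree()).addi(s, e, gid)
            span = idx.gene_spans.get(gid)
            if span is None:
                idx.gene_spans[gid] = (chain.chrom, chain.start, chain.end, chain.strand)
            else:
                idx.gene_spans[gid] = (
                    span[0], min(span[1], chain.start), max(span[2], chain.end), span[3],
                )
        for gid, (chrom, s, e, strand) in idx.gene_spans.items():
            idx._gene_trees.setdefault(chrom, IntervalTree()).addi(s, e, (gid, strand))
        return idx

    # --- queries ---------------------------------------------------------
    def exon_overlap_genes(self, chain: ExonChain) -> set:
        tree = self._exon_trees.get((chain.chrom, chain.strand))
        if tree is None:
            return set()
        genes: set = set()
        for s, e in chain.exons:
            genes.update(iv.data for iv in tree.overlap(s, e))
        return genes

    def genes_at(self, chrom: str, pos: int) -> set:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}

    def overlapping_genes(self, chain: ExonChain) -> set:
        """(gene, strand) pairs whose span intersects the chain span."""
        tree = self._gene_trees.get(chain.chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(chain.start, chain.end)}

    def contained_in_intron(self, chain: ExonChain) -> bool:
        tree = self._intron_trees.get((chain.chrom, chain.strand))
        if tree is None:
            return False
        return any(
            iv.begin <= chain.start and chain.end <= iv.end
            for iv in tree.overlap(chain.start, chain.end)
        )


def _chain_tuple(chain: ExonChain):
    return (
        chain.chrom,
        chain.strand,
        tuple((j.donor_pos, j.acceptor_pos) for j in chain.junctions),
    )


def _is_subchain(query, reference) -> bool:
    """query junction tuple appears as a contiguous run inside reference."""
    k, n = len(query), len(reference)
    if k == 0 or k > n:
        return False
    return any(reference[i : i + k] == query for i in range(n - k + 1))


def classify_isoform(chain: ExonChain, ref: ReferenceIndex) -> str:
    """Assign exactly one category to the query chain (ladder above)."""
    if not chain.is_mono:
        key = _chain_tuple(chain)
        if key in ref.junction_chains:
            return "FSM"
        # fusion: exonic overlap with >= 2 genes plus a bridging junction
        genes = ref.exon_overlap_genes(chain)
        if len(genes) >= 2 and _has_bridging_junction(chain, ref, genes):
            return "fusion"
        q = key[2]
        for t in ref.transcripts.values():
            if t.chrom == chain.chrom and t.strand == chain.strand and _is_subchain(
                q, tuple((j.donor_pos, j.acceptor_pos) for j in t.junctions)
            ):
                return "ISM"
        all_known = all(
            d in ref.donor_set and a in ref.acceptor_set
            for d, a in (_donor_acceptor(j) for j in chain.junctions)
        )
        return "NIC" if all_known else "NNIC"

    # mono-exon ladder
    if ref.exon_overlap_genes(chain):
        return "genic"
    if ref.contained_in_intron(chain):
        return "genic_intron"
    overlapping = ref.overlapping_genes(chain)
    if overlapping:
        if all(strand != chain.strand for _, strand in overlapping):
            return "antisense"
        return "genic"  # inside a same-strand gene but exon-free overlap region
    return "intergenic"


def _has_bridging_junction(chain: ExonChain, ref: ReferenceIndex, genes: set) -> bool:
    spans = {g: ref.gene_spans[g] for g in genes}
    for j in chain.junctions:
        left = {g for g, (c, s, e, st) in spans.items() if s <= j.donor_pos < e}
        right = {g for g, (c, s, e, st) in spans.items() if s <= j.acceptor_pos - 1 < e}
        if any(gl != gr for gl in left for gr in right):
            return True
    return False


# ---------------------------------------------------------------------------
# Junction motifs
# ---------------------------------------------------------------------------

_MOTIFS = {("GT", "AG"): "GT-AG", ("GC", "AG"): "GC-AG", ("AT", "AC"): "AT-AC"}


def junction_motif(genome, j: SpliceJunction) -> str:
    """Motif class of the intron: GT-AG, GC-AG, AT-AC or noncanonical.

    ``genome`` is a mapping chrom -> sequence (plain dict or pyfaidx
    record access).  The first/last two intronic bases are read in
    transcript orientation (reverse-complemented on '-')."""
    seq = genome[j.chrom]
    if j.donor_pos < 0 or j.acceptor_pos > len(seq):
        raise ValueError(f"junction {j} outside sequence bounds")
    left = str(seq[j.donor_pos : j.donor_pos + 2]).upper()
    right = str(seq[j.acceptor_pos - 2 : j.acceptor_pos]).upper()
    if j.strand == "+":
        pair = (left, right)
    else:
        pair = (revcomp(right), revcomp(left))
    return _MOTIFS.get(pair, "noncanonical")


def artifact_labels(isoforms: dict, ref: ReferenceIndex, genome) -> dict:
    """Rule-based artifact labels per isoform id.

    TP: full-splice match.  TN: carries >= 1 junction that is both novel
    (absent from the reference junction set) and non-canonical in motif.
    Everything else is unlabeled.  The built-in filter removes TN-labeled
    isoforms; the labels can also train an external classifier.
    """
    labels = {}
    for iid, chain in isoforms.items():
        if not chain.is_mono and _chain_tuple(chain) in ref.junction_chains:
            labels[iid] = "TP"
            continue
        tn = False
        for j in chain.junctions:
            novel = (j.chrom, j.strand, j.donor_pos, j.acceptor_pos) not in ref.junction_set
            if novel and junction_motif(genome, j) == "noncanonical":
                tn = True
                break
        labels[iid] = "TN" if tn else "unlabeled"
    return labels
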