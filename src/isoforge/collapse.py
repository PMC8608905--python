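"""Intra- and inter-sample isoform collapsing, detection calls, unique
full-length read counts (PBcount), and the prefilters.

The collapsing logic follows the multi-sample assembly strategy for
long-read transcriptomes:

* multi-exon reads merge when their splice-junction chains are identical
  (end coordinates ignored; the most upstream TSS and most downstream
  TTS of the merged reads become the isoform ends, all original ends are
  retained);
* within one sample, a multi-exon isoform whose chain is a 5'-truncated
  suffix of a longer, compatible isoform is absorbed as a fragment of it
  — RNA decay makes such fragments untrustworthy as independent
  isoforms;
* across samples, truncated survivors are NOT absorbed by longer
  isoforms of other samples unless the junction chains are identical:
  a chain observed intact in one sample is real evidence of that
  exon-intron structure;
* mono-exon reads merge only with other mono-exon reads, by same-strand
  genomic overlap (connected components), never into multi-exon
  isoforms.

Detection in a sample requires a non-truncated supporting read; PBcount
sums FL counts of reads linked to exactly one isoform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_model import (
    ExonChain,
    chains_overlap,
    exons_overlap,
    is_five_prime_truncation,
    junction_key,
)

__all__ = [
    "CollapsedIsoform",
    "PrefilterConfig",
    "collapse_sample",
    "merge_cohort",
    "assign_gene_groups",
    "call_detection",
    "compute_pbcount",
    "prefilter_major",
    "relative_expression_filter",
]


@dataclass
class CollapsedIsoform:
    """A merged isoform with aggregated ends and read links.

    ``read_links`` maps (sample_id, read_id) -> 'unique' or 'ambiguous';
    ``truncated_reads`` flags links contributed by absorbed 5'-truncated
    fragments (they support expression but not detection).
    """

    isoform_id: str
    chain: ExonChain
    gene_group_id: str = ""
    supporting_tss: list = field(default_factory=list)
    supporting_tts: list = field(default_factory=list)
    read_links: dict = field(default_factory=dict)
    truncated_reads: set = field(default_factory=set)
    detected: dict = field(default_factory=dict)
    pbcount: dict = field(default_factory=dict)

    @property
    def key(self) -> str:
        return junction_key(self.chain)

    @property
    def is_mono(self) -> bool:
        return self.chain.is_mono


@dataclass
class PrefilterConfig:
    min_pbcount: int = 5
    max_per_gene: int = 10
    rel_expr_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.min_pbcount < 0 or self.max_per_gene < 0 or self.rel_expr_floor < 0:
            raise ValueError("prefilter thresholds must be >= 0")


def _sort_key(iso: CollapsedIsoform):
    return (iso.chain.chrom, iso.chain.start, iso.chain.end, iso.key)


def _aggregate_ends(iso: CollapsedIsoform) -> None:
    """Extend the chain to the most upstream TSS / most downstream TTS
    among supporting ends (genomic min start, max end)."""
    if iso.chain.strand == "+":
        new_start = min(iso.supporting_tss)
        new_end = max(iso.supporting_tts)
    else:
        new_start = min(iso.supporting_tts)
        new_end = max(iso.supporting_tss)
    if not iso.chain.is_mono:
        # never let an aggregated end cross the first/last junction
        new_start = min(new_start, iso.chain.exons[0][0])
        new_end = max(new_end, iso.chain.exons[-1][1])
    iso.chain = iso.chain.with_ends(new_start, new_end)


def collapse_sample(reads) -> list:
    """Collapse the reads of one sample into isoforms.

    All reads must be non-chimeric and from the same sample.
    """
    samples = {r.sample_id for r in reads}
    if len(samples) > 1:
        raise ValueError(f"collapse_sample got reads from multiple samples: {sorted(samples)}")
    if any(r.is_chimeric for r in reads):
        raise ValueError("collapse_sample does not accept chimeric reads")

    multi = [r for r in reads if not r.chain.is_mono]
    mono = [r for r in reads if r.chain.is_mono]

    # (1) merge multi-exon reads by junction chain
    groups: dict = {}
    for r in multi:
        groups.setdefault(junction_key(r.chain), []).append(r)

    isoforms = []
    for key in sorted(groups):
        grp = sorted(groups[key], key=lambda r: r.read_id)
        chain = grp[0].chain
        iso = CollapsedIsoform(isoform_id="", chain=ExonChain(chain.chrom, chain.strand, chain.exons))
        for r in grp:
            iso.supporting_tss.append(r.chain.tss)
            iso.supporting_tts.append(r.chain.tts)
            iso.read_links[(r.sample_id, r.read_id)] = "unique"
        _aggregate_ends(iso)
        isoforms.append(iso)

    # (2) absorb 5'-truncated isoforms into longer compatible ones
    survivors, absorbed = [], []
    targets_of: dict = {}
    for i, iso in enumerate(isoforms):
        tgts = [
            j
            for j, other in enumerate(isoforms)
            if j != i and is_five_prime_truncation(iso.chain, other.chain)
        ]
        if tgts:
            targets_of[i] = tgts
            absorbed.append(i)
        else:
            survivors.append(i)

    for i in absorbed:
        tgts = targets_of[i]
        kind = "unique" if len(tgts) == 1 else "ambiguous"
        frag = isoforms[i]
        for j in tgts:
            tgt = isoforms[j]
            for link in frag.read_links:
                tgt.read_links[link] = kind
                tgt.truncated_reads.add(link)
            tgt.supporting_tts.extend(frag.supporting_tts)
            # fragment TSSs are decay artifacts; not aggregated into the ends
    out = [isoforms[i] for i in survivors]
    for iso in out:
        _aggregate_ends(iso)

    # (3) mono-exon reads: connected components by same-strand overlap
    out.extend(_merge_mono_items([(r.chain, {(r.sample_id, r.read_id): "unique"},
                                   [r.chain.tss], [r.chain.tts], set()) for r in mono]))
    out.sort(key=_sort_key)
    for n, iso in enumerate(out, 1):
        iso.isoform_id = iso.isoform_id or f"iso{n:06d}"
    return out


def _merge_mono_items(items) -> list:
    """items: (chain, read_links, tss, tts, truncated) tuples -> merged
    mono-exon CollapsedIsoforms via same-strand overlap components."""
    items = sorted(items, key=lambda t: (t[0].chrom, t[0].strand, t[0].start, t[0].end))
    merged = []
    for chain, links, tss, tts, trunc in items:
        placed = False
        if merged:
            last = merged[-1]
            if (
                last.chain.chrom == chain.chrom
                and last.chain.strand == chain.strand
                and chain.start < last.chain.end
            ):
                # sorted sweep: overlap with the growing component
                last.chain = ExonChain(
                    chain.chrom, chain.strand,
                    [(last.chain.start, max(last.chain.end, chain.end))],
                )
                last.read_links.update(links)
                last.truncated_reads.update(trunc)
                last.supporting_tss.extend(tss)
                last.supporting_tts.extend(tts)
                placed = True
        if not placed:
            merged.append(
                CollapsedIsoform(
                    isoform_id="",
                    chain=ExonChain(chain.chrom, chain.strand, chain.exons),
                    supporting_tss=list(tss),
                    supporting_tts=list(tts),
                    read_links=dict(links),
                    truncated_reads=set(trunc),
                )
            )
    return merged


def merge_cohort(per_sample: dict) -> list:
    """Merge per-sample isoform lists into a cohort transcriptome.

    Multi-exon isoforms merge across samples only on identical junction
    chains — truncated survivors of one sample stay independent of longer
    isoforms of other samples.  Mono-exon isoforms merge by same-strand
    overlap.  Gene groups and PB.<gene>.<iso> ids are assigned.
    """
    multi_groups: dict = {}
    mono_items = []
    for sample in sorted(per_sample):
        for iso in per_sample[sample]:
            if iso.is_mono:
                mono_items.append(
                    (iso.chain, iso.read_links, iso.supporting_tss, iso.supporting_tts,
                     iso.truncated_reads)
                )
            else:
                multi_groups.setdefault(iso.key, []).append(iso)

    cohort = []
    for key in sorted(multi_groups):
        grp = multi_groups[key]
        merged = CollapsedIsoform(
            isoform_id="",
            chain=ExonChain(grp[0].chain.chrom, grp[0].chain.strand, grp[0].chain.exons),
        )
        for iso in grp:
            merged.supporting_tss.extend(iso.supporting_tss)
            merged.supporting_tts.extend(iso.supporting_tts)
            merged.read_links.update(iso.read_links)
            merged.truncated_reads.update(iso.truncated_reads)
        _aggregate_ends(merged)
        cohort.append(merged)

    cohort.extend(_merge_mono_items(mono_items))
    cohort.sort(key=_sort_key)
    assign_gene_groups(cohort)
    return cohort


def assign_gene_groups(isoforms) -> None:
    """Gene groups = connected components of isoforms sharing >= 1
    splice junction or overlapping exonically on the same strand.
    Ids: G<g> for groups, PB.<g>.<i> for isoforms (positional order)."""
    n = len(isoforms)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_junction: dict = {}
    for i, iso in enumerate(isoforms):
        for j in iso.chain.junctions:
            by_junction.setdefault((j.chrom, j.strand, j.donor_pos, j.acceptor_pos), []).append(i)
    for members in by_junction.values():
        for other in members[1:]:
            union(members[0], other)

    # same-strand exonic overlap via a sorted sweep per (chrom, strand)
    order = sorted(range(n), key=lambda i: (isoforms[i].chain.chrom, isoforms[i].chain.strand,
                                            isoforms[i].chain.start))
    active: list = []
    prev_key = None
    for i in order:
        ch = isoforms[i].chain
        key = (ch.chrom, ch.strand)
        if key != prev_key:
            active = []
            prev_key = key
        active = [a for a in active if isoforms[a].chain.end > ch.start]
        for a in active:
            if exons_overlap(isoforms[a].chain, ch):
                union(a, i)
        active.append(i)

    roots = sorted({find(i) for i in range(n)}, key=lambda r: _sort_key(isoforms[r]))
    gid_of_root = {r: f"G{k + 1:05d}" for k, r in enumerate(roots)}
    counters: dict = {}
    for i in sorted(range(n), key=lambda i: _sort_key(isoforms[i])):
        gid = gid_of_root[find(i)]
        counters[gid] = counters.get(gid, 0) + 1
        isoforms[i].gene_group_id = gid
        isoforms[i].isoform_id = f"PB.{gid[1:].lstrip('0') or '0'}.{counters[gid]}"


def call_detection(isoforms, reads_by_sample: dict) -> None:
    """Per-sample detection: a multi-exon isoform is detected in a sample
    iff the sample has a read whose full junction chain matches; a
    mono-exon isoform iff a mono-exon read's span is contained in it
    (same strand).  Truncated fragments do not count."""
    multi_index: dict = {}
    mono_list = []
    for iso in isoforms:
        if iso.is_mono:
            mono_list.append(iso)
        else:
            multi_index[iso.key] = iso
        iso.detected = {s: False for s in reads_by_sample}
    mono_list.sort(key=lambda i: (i.chain.chrom, i.chain.strand, i.chain.start))
    for sample, reads in reads_by_sample.items():
        for r in reads:
            if r.is_chimeric:
                continue
            if r.chain.is_mono:
                for iso in mono_list:
                    if (
                        iso.chain.chrom == r.chain.chrom
                        and iso.chain.strand == r.chain.strand
                        and iso.chain.start <= r.chain.start
                        and r.chain.end <= iso.chain.end
                    ):
                        iso.detected[sample] = True
            else:
                iso = multi_index.get(junction_key(r.chain))
                if iso is not None:
                    iso.detected[sample] = True


def compute_pbcount(isoforms, reads_by_sample: dict) -> None:
    """pbcount[sample] = sum of FL counts of reads linked uniquely to the
    isoform; ambiguously linked reads contribute nothing anywhere."""
    fl: dict = {}
    for sample, reads in reads_by_sample.items():
        for r in reads:
            fl[(sample, r.read_id)] = r.fl_count
    for iso in isoforms:
        counts = {s: 0 for s in reads_by_sample}
        for (sample, rid), kind in iso.read_links.items():
            if kind == "unique" and sample in counts:
                counts[sample] += fl.get((sample, rid), 0)
        iso.pbcount = counts


def prefilter_major(isoforms, cfg: PrefilterConfig | None = None,
                    require_all_samples: bool = True) -> list:
    """Major-isoform prefilter.

    Per gene: candidates are isoforms ranked 1st or 2nd by pbcount in at
    least one sample (competition ranking) AND with pbcount >=
    cfg.min_pbcount in all samples (or in total if
    ``require_all_samples`` is False); up to cfg.max_per_gene survive in
    descending total-pbcount order.  Genes with zero survivors rescue
    their single largest-pbcount isoform.  Returns the surviving subset.
    """
    cfg = cfg or PrefilterConfig()
    by_gene: dict = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_group_id, []).append(iso)

    kept = []
    for gid in sorted(by_gene):
        members = sorted(by_gene[gid], key=lambda i: (-sum(i.pbcount.values()), i.isoform_id))
        samples = sorted({s for iso in members for s in iso.pbcount})
        top2: set = set()
        for s in samples:
            vals = [iso.pbcount.get(s, 0) for iso in members]
            for iso, v in zip(members, vals):
                if sum(1 for w in vals if w > v) < 2:
                    top2.add(iso.isoform_id)
        def passes_floor(iso):
            if require_all_samples:
                return all(iso.pbcount.get(s, 0) >= cfg.min_pbcount for s in samples)
            return sum(iso.pbcount.values()) >= cfg.min_pbcount
        candidates = [iso for iso in members if iso.isoform_id in top2 and passes_floor(iso)]
        survivors = candidates[: cfg.max_per_gene]
        if not survivors and members:
            survivors = [members[0]]  # rescue the top-pbcount isoform
        kept.extend(survivors)
    return kept


def relative_expression_filter(expr, gene_of: dict, floor: float = 0.1) -> list:
    """Keep isoforms whose mean-across-samples share of their gene's
    total expression is >= ``floor`` (shares exactly at the floor kept).

    ``expr``: pandas DataFrame, isoforms x samples, non-negative.
    ``gene_of``: isoform id -> gene id.  Returns kept isoform ids.
    """
    import numpy as np
    import pandas as pd

    expr = expr.astype(float)
    if (expr.values < 0).any():
        raise ValueError("expression must be non-negative")
    genes = pd.Series({i: gene_of[i] for i in expr.index})
    totals = expr.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = (expr / totals).fillna(0.0)
    mean_share = shares.mean(axis=1)
    return [i for i in expr.index if mean_share[i] >= floor]
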