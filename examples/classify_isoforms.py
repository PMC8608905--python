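"""Categorize query isoforms against a reference annotation.

Builds FSM / ISM / NIC / NNIC examples from a toy annotation and runs
the classification ladder plus the rule-based artifact labels.
"""

from isoforge import make_toy_reference
from isoforge.classify import ReferenceIndex, artifact_labels, classify_isoform
from isoforge.genome_model import ExonChain

toy = make_toy_reference(n_genes=3, isoforms_per_gene=3, seed=5)
idx = ReferenceIndex.from_annotation(toy.annotation)

t = next(c for c in toy.annotation.transcripts.values() if len(c.exons) >= 5)
queries = {
    "exact_copy": ExonChain(t.chrom, t.strand, t.exons),
    "interior_fragment": ExonChain(t.chrom, t.strand, t.exons[1:4]),
    "exon_skip": ExonChain(t.chrom, t.strand, [t.exons[0], *t.exons[2:]]),
    "shifted_donor": ExonChain(
        t.chrom, t.strand, [(t.exons[0][0], t.exons[0][1] - 5), *t.exons[1:]]
    ),
    "intron_fragment": ExonChain(
        t.chrom, t.strand, [(t.exons[0][1] + 10, t.exons[1][0] - 10)]
    ),
}

labels = artifact_labels(queries, idx, toy.genome)
for name, chain in queries.items():
    cat = classify_isoform(chain, idx)
    print(f"{name:18s} -> {cat:12s} artifact_label={labels[name]}")

# exact_copy is FSM (and a TP for filter training); the interior
# fragment is ISM; the exon skip reuses known donors/acceptors (NIC
# unless a sibling annotates it); the shifted donor creates a novel
# splice site (NNIC) and, when its motif is non-canonical, a TN that
# the built-in filter would remove.
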