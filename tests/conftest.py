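import pytest

from isoforge import make_toy_reference
from isoforge.classify import ReferenceIndex


@pytest.fixture(scope="session")
def toy():
    """Small toy genome + annotation shared across read-only tests."""
    return make_toy_reference(n_genes=6, isoforms_per_gene=3, seed=11, rearrange=True)


@pytest.fixture(scope="session")
def toy_index(toy):
    return ReferenceIndex.from_annotation(toy.annotation)


def chain_identity(chain):
    """Canonical identity of a chain for set comparisons: junction chain
    for multi-exon, full span for mono-exon."""
    if chain.is_mono:
        return (chain.chrom, chain.strand, "mono", chain.start, chain.end)
    return (
        chain.chrom,
        chain.strand,
        tuple((j.donor_pos, j.acceptor_pos) for j in chain.junctions),
    )
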