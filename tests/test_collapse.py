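"""Isoform collapsing: merging, truncation absorption, detection,
PBcount and the prefilters."""

import numpy as np
import pandas as pd
import pytest

from isoforge import (
    ErrorModel,
    PrefilterConfig,
    call_detection,
    collapse_sample,
    compute_pbcount,
    make_toy_reference,
    merge_cohort,
    perfect_read_records,
    prefilter_major,
    relative_expression_filter,
    simulate_reads,
)
from isoforge.collapse import CollapsedIsoform, assign_gene_groups
from isoforge.genome_model import ExonChain, is_five_prime_truncation
from isoforge.io_formats import ReadRecord

from conftest import chain_identity


def read(rid, exons, strand="+", sample="s1", fl=1, chrom="chr1"):
    return ReadRecord(rid, sample, ExonChain(chrom, strand, exons), fl_count=fl)


class TestCollapseSample:
    def test_same_junctions_merge_with_extreme_ends(self):
        a = read("a", [(100, 200), (300, 400)])
        b = read("b", [(120, 200), (300, 390)])
        isos = collapse_sample([a, b])
        assert len(isos) == 1
        iso = isos[0]
        assert iso.chain.exons == ((100, 200), (300, 400))
        assert sorted(iso.supporting_tss) == [100, 120]
        assert sorted(iso.supporting_tts) == [390, 400]

    def test_truncated_read_absorbed(self):
        full = read("full", [(0, 10), (20, 30), (40, 50)])
        frag = read("frag", [(22, 30), (40, 50)])
        isos = collapse_sample([full, frag])
        assert len(isos) == 1
        assert ("s1", "frag") in isos[0].read_links
        assert ("s1", "frag") in isos[0].truncated_reads
        assert isos[0].read_links[("s1", "frag")] == "unique"

    def test_multiply_compatible_fragment_is_ambiguous(self):
        long1 = read("l1", [(0, 10), (20, 30), (40, 50)])
        long2 = read("l2", [(5, 12), (20, 30), (40, 50)])
        frag = read("frag", [(22, 30), (40, 50)])
        isos = collapse_sample([long1, long2, frag])
        assert len(isos) == 2
        for iso in isos:
            assert iso.read_links[("s1", "frag")] == "ambiguous"

    def test_mono_exon_overlap_components(self):
        isos = collapse_sample([read("a", [(100, 300)]), read("b", [(250, 500)])])
        assert len(isos) == 1
        assert isos[0].chain.exons == ((100, 500),)

    def test_mono_never_merges_into_multi(self):
        isos = collapse_sample([read("a", [(100, 300)]), read("b", [(100, 200), (250, 400)])])
        assert len(isos) == 2

    def test_opposite_strand_mono_not_merged(self):
        isos = collapse_sample([read("a", [(100, 300)]), read("b", [(150, 400)], strand="-")])
        assert len(isos) == 2

    def test_chimeric_read_rejected(self):
        r = read("a", [(100, 300)])
        r.is_chimeric = True
        r.segments = r.segments * 2
        with pytest.raises(ValueError):
            collapse_sample([r])

    def test_order_invariance(self):
        reads = [
            read("a", [(100, 200), (300, 400)]),
            read("b", [(120, 200), (300, 390)]),
            read("c", [(320, 400)]),
            read("d", [(0, 10), (20, 30), (40, 50)]),
            read("e", [(22, 30), (40, 50)]),
        ]
        first = collapse_sample(reads)
        second = collapse_sample(list(reversed(reads)))
        assert [chain_identity(i.chain) for i in first] == [
            chain_identity(i.chain) for i in second
        ]
        assert [i.read_links for i in first] == [i.read_links for i in second]

    def test_idempotence_on_cohort(self):
        """Re-collapsing the reads of a collapsed set changes nothing."""
        reads = [
            read("a", [(100, 200), (300, 400)]),
            read("b", [(120, 200), (300, 390)]),
            read("c", [(600, 900)]),
        ]
        once = collapse_sample(reads)
        again_reads = [
            read(f"x{k}", list(i.chain.exons), strand=i.chain.strand) for k, i in enumerate(once)
        ]
        twice = collapse_sample(again_reads)
        assert [chain_identity(i.chain) for i in once] == [
            chain_identity(i.chain) for i in twice
        ]


class TestMergeCohort:
    def test_identical_chains_merge_across_samples(self):
        s1 = collapse_sample([read("a", [(100, 200), (300, 400)], sample="s1")])
        s2 = collapse_sample([read("b", [(110, 200), (300, 380)], sample="s2")])
        cohort = merge_cohort({"s1": s1, "s2": s2})
        assert len(cohort) == 1
        assert cohort[0].chain.exons == ((100, 200), (300, 400))

    def test_truncated_survivor_stays_independent_across_samples(self):
        # sample 1 has only the truncated chain; sample 2 the full chain
        s1 = collapse_sample([read("a", [(22, 30), (40, 50)], sample="s1")])
        s2 = collapse_sample([read("b", [(0, 10), (20, 30), (40, 50)], sample="s2")])
        cohort = merge_cohort({"s1": s1, "s2": s2})
        assert len(cohort) == 2

    def test_mono_exon_merge_across_samples(self):
        s1 = collapse_sample([read("a", [(100, 300)], sample="s1")])
        s2 = collapse_sample([read("b", [(250, 500)], sample="s2")])
        cohort = merge_cohort({"s1": s1, "s2": s2})
        assert len(cohort) == 1 and cohort[0].chain.exons == ((100, 500),)

    def test_gene_groups_by_shared_junction_and_overlap(self):
        s1 = collapse_sample(
            [
                read("a", [(100, 200), (300, 400), (600, 700)], sample="s1"),
                read("b", [(150, 200), (300, 500)], sample="s1"),  # shares junction
                read("c", [(450, 520), (600, 700)], sample="s1"),  # exonic overlap with b
                read("d", [(10000, 10100), (10200, 10300)], sample="s1"),  # separate gene
            ]
        )
        cohort = merge_cohort({"s1": s1})
        gids = {i.isoform_id: i.gene_group_id for i in cohort}
        groups = {}
        for iso in cohort:
            groups.setdefault(iso.gene_group_id, []).append(iso)
        sizes = sorted(len(v) for v in groups.values())
        assert sizes == [1, 3]
        assert all(i.isoform_id.startswith("PB.") for i in cohort)

    def test_sample_order_invariance(self):
        reads = {
            "s1": [read("a", [(100, 200), (300, 400)], sample="s1")],
            "s2": [read("b", [(110, 200), (300, 380)], sample="s2")],
        }
        c1 = merge_cohort({s: collapse_sample(r) for s, r in reads.items()})
        c2 = merge_cohort({s: collapse_sample(r) for s, r in reversed(reads.items())})
        assert [chain_identity(i.chain) for i in c1] == [chain_identity(i.chain) for i in c2]


class TestDetectionAndPbcount:
    def setup_cohort(self):
        r_full = read("full", [(0, 10), (20, 30), (40, 50)], sample="s1")
        r_trunc = read("tr", [(22, 30), (40, 50)], sample="s2")
        reads_by_sample = {"s1": [r_full], "s2": [r_trunc]}
        s1 = collapse_sample([r_full])
        s2 = collapse_sample([r_trunc])
        cohort = merge_cohort({"s1": s1, "s2": s2})
        return cohort, reads_by_sample

    def test_truncated_only_sample_counts_as_detected_for_its_own_chain(self):
        cohort, rbs = self.setup_cohort()
        call_detection(cohort, rbs)
        by_n_junc = {len(i.chain.junctions): i for i in cohort}
        full_iso, trunc_iso = by_n_junc[2], by_n_junc[1]
        assert full_iso.detected == {"s1": True, "s2": False}
        assert trunc_iso.detected == {"s1": False, "s2": True}

    def test_truncated_supporting_read_does_not_detect(self):
        # both reads in one sample: fragment absorbed, isoform detected
        # only where a full-chain read exists
        r_full = read("full", [(0, 10), (20, 30), (40, 50)], sample="s1")
        r_trunc = read("tr", [(22, 30), (40, 50)], sample="s2")
        s1 = collapse_sample([r_full, read("tr2", [(22, 30), (40, 50)], sample="s1")])
        assert len(s1) == 1  # absorbed intra-sample
        cohort = merge_cohort({"s1": s1})
        call_detection(cohort, {"s1": [r_full], "s2": [r_trunc]})
        # s2's fragment matches no cohort chain fully (only chain is the long one)
        assert cohort[0].detected == {"s1": True, "s2": False}

    def test_mono_exon_detection_requires_containment(self):
        r1 = read("a", [(100, 300)], sample="s1")
        r2 = read("b", [(250, 500)], sample="s1")
        cohort = merge_cohort({"s1": collapse_sample([r1, r2])})
        contained = read("c", [(150, 450)], sample="s2")
        escaping = read("d", [(50, 450)], sample="s3")
        call_detection(cohort, {"s1": [r1, r2], "s2": [contained], "s3": [escaping]})
        assert cohort[0].detected == {"s1": True, "s2": True, "s3": False}

    def test_pbcount_sums_unique_fl_counts(self):
        a = read("a", [(100, 200), (300, 400)], fl=3)
        b = read("b", [(100, 200), (300, 400)], fl=2)
        cohort = merge_cohort({"s1": collapse_sample([a, b])})
        compute_pbcount(cohort, {"s1": [a, b]})
        assert cohort[0].pbcount == {"s1": 5}

    def test_ambiguous_reads_contribute_zero_everywhere(self):
        long1 = read("l1", [(0, 10), (20, 30), (40, 50)])
        long2 = read("l2", [(5, 12), (20, 30), (40, 50)])
        frag = read("frag", [(22, 30), (40, 50)], fl=10)
        cohort = merge_cohort({"s1": collapse_sample([long1, long2, frag])})
        compute_pbcount(cohort, {"s1": [long1, long2, frag]})
        assert sorted(i.pbcount["s1"] for i in cohort) == [1, 1]

    def test_conservation_inequality(self):
        rng = np.random.default_rng(0)
        toy = make_toy_reference(n_genes=10, isoforms_per_gene=3, seed=9)
        txome = toy.transcript_sequences()
        reads, truth = simulate_reads(txome, {t: 1.0 for t in txome}, 500,
                                      err=ErrorModel(0, 0, 0), seed=4)
        recs = perfect_read_records(truth, toy.annotation, "s1")
        cohort = merge_cohort({"s1": collapse_sample(recs)})
        compute_pbcount(cohort, {"s1": recs})
        total_pb = sum(i.pbcount["s1"] for i in cohort)
        total_fl = sum(r.fl_count for r in recs)
        assert total_pb <= total_fl
        # no ambiguity in this clean fixture -> equality
        assert total_pb == total_fl


class TestPrefilters:
    def make_gene(self, pbcounts):
        """pbcounts: isoform -> sample -> count; all in one gene group."""
        isos = []
        for k, (iid, pc) in enumerate(sorted(pbcounts.items())):
            iso = CollapsedIsoform(
                isoform_id=iid,
                chain=ExonChain("chr1", "+", [(100 * k, 100 * k + 50), (5000, 5100)]),
                gene_group_id="G1",
            )
            iso.pbcount = dict(pc)
            isos.append(iso)
        return isos

    def test_up_to_ten_kept(self):
        # 12 isoforms, each top-2 in one of 6 samples, all above the floor
        pb = {
            f"i{k:02d}": {f"s{j}": (100 if j == k // 2 else 5) for j in range(6)}
            for k in range(12)
        }
        kept = prefilter_major(self.make_gene(pb))
        assert len(kept) == 10

    def test_rescue_single_top_isoform(self):
        pb = {"i1": {"s1": 4, "s2": 1}, "i2": {"s1": 2, "s2": 2}}
        kept = prefilter_major(self.make_gene(pb), PrefilterConfig(min_pbcount=5))
        assert [i.isoform_id for i in kept] == ["i1"]

    def test_never_top2_isoform_dropped(self):
        pb = {
            "iA": {"s1": 50, "s2": 10},
            "iB": {"s1": 10, "s2": 50},
            "iC": {"s1": 8, "s2": 8},  # third in both samples
        }
        kept = prefilter_major(self.make_gene(pb))
        assert sorted(i.isoform_id for i in kept) == ["iA", "iB"]

    def test_min_pbcount_in_all_samples(self):
        pb = {"iA": {"s1": 50, "s2": 4}, "iB": {"s1": 10, "s2": 10}}
        kept = prefilter_major(self.make_gene(pb))
        assert [i.isoform_id for i in kept] == ["iB"]

    def test_relative_expression_floor(self):
        expr = pd.DataFrame(
            {"s1": [85.0, 10.0, 5.0], "s2": [85.0, 10.0, 5.0]},
            index=["a", "b", "c"],
        )
        gene_of = {"a": "g", "b": "g", "c": "g"}
        kept = relative_expression_filter(expr, gene_of, floor=0.1)
        assert kept == ["a", "b"]  # share exactly 0.1 is kept

    def test_single_isoform_gene_kept(self):
        expr = pd.DataFrame({"s1": [3.0]}, index=["a"])
        assert relative_expression_filter(expr, {"a": "g"}) == ["a"]

    def test_zero_total_gene_keeps_nothing(self):
        expr = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        assert relative_expression_filter(expr, {"a": "g", "b": "g"}) == []

    def test_negative_expression_is_error(self):
        expr = pd.DataFrame({"s1": [-1.0]}, index=["a"])
        with pytest.raises(ValueError):
            relative_expression_filter(expr, {"a": "g"})


class TestBruteForceAbsorption:
    def test_absorption_matches_suffix_oracle(self):
        """Intra-sample absorption compared against brute-force
        enumeration of suffix relations among the collapsed chains."""
        toy = make_toy_reference(n_genes=8, isoforms_per_gene=4, seed=21)
        txome = toy.transcript_sequences()
        from isoforge import DecayModel

        reads, truth = simulate_reads(
            txome, {t: 1.0 for t in txome}, 600, err=ErrorModel(0, 0, 0),
            decay=DecayModel(1.5, 400), seed=6,
        )
        recs = perfect_read_records(truth, toy.annotation, "s1")
        multi = [r for r in recs if not r.chain.is_mono]
        # group stage only: distinct junction chains
        from isoforge.genome_model import junction_key

        chains = {}
        for r in multi:
            chains.setdefault(junction_key(r.chain), r.chain)
        keys = sorted(chains)
        absorbed_oracle = set()
        for k in keys:
            c = chains[k]
            for k2 in keys:
                if k2 == k:
                    continue
                c2 = chains[k2]
                if (
                    not c.is_mono and not c2.is_mono
                    and c.chrom == c2.chrom and c.strand == c2.strand
                    and len(c.junctions) < len(c2.junctions)
                ):
                    sj = c.junctions
                    lj = c2.junctions
                    suffix = lj[-len(sj):] if c.strand == "+" else lj[: len(sj)]
                    if suffix == sj and c2.start <= c.start and c.end <= c2.end:
                        absorbed_oracle.add(k)
                        break
        surviving_oracle = set(keys) - absorbed_oracle
        isos = collapse_sample(multi)
        surviving = {junction_key(i.chain) for i in isos}
        # keys contain ends for mono only; multi keys are end-free, comparable
        assert surviving == surviving_oracle
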