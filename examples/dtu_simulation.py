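"""Run the differential-transcript-usage simulation loop.

Assigns DTU labels under the sweep design (10% of genes, fold change 4,
8 samples per group), simulates negative-binomial counts, runs the
built-in multinomial DTU test with stage-wise correction, and scores
the calls against the truth.
"""

from isoforge import (
    SimulationDesign,
    assign_sweep,
    dtu_test,
    evaluate_dtu,
    simulate_counts,
)

genes = {f"g{i:03d}": [f"g{i:03d}.t{j}" for j in range(3)] for i in range(300)}
design = SimulationDesign(fold_change=4.0, seed=1)
truth = assign_sweep(genes, design)
print(f"genes                : {len(genes)} ({len(truth.dtu_genes)} DTU)")

counts, groups = simulate_counts(truth, depth=30_000, dispersion=0.05,
                                 n_samples_per_group=8, seed=2)
gene_map = {iso: g for g, isos in genes.items() for iso in isos}
gene_res, iso_res = dtu_test(counts, gene_map, groups)

called_genes = set(gene_res.index[(gene_res["q"] < 0.05).fillna(False)])
called_isos = set(iso_res.index[(iso_res["q"] < 0.05).fillna(False)])
result = evaluate_dtu(called_isos, truth)
print(f"genes called (q<.05) : {len(called_genes)}")
print(f"isoforms called      : {len(called_isos)}")
print(f"isoform precision    : {result['precision']:.3f}")
print(f"isoform recall       : {result['recall']:.3f}")
# Recall is essentially perfect at this depth.  Precision suffers from
# two honest effects: the multinomial test assumes no extra-Poisson
# noise, so biological dispersion (0.05 here) inflates gene-level calls;
# and in true DTU genes the non-designated isoforms' proportions shift
# as a side effect of the designated pair swapping, so they too can
# reach significance.  Re-run with dispersion=0.0 to see the first
# effect vanish.
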