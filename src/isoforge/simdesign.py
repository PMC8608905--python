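"""Differential-expression / differential-transcript-usage simulation
designs, negative-binomial count generation, a built-in DTU test and
its evaluation.

Two label-assignment procedures are provided:

* a parameter sweep (`assign_sweep`): all isoforms at relative
  expression 1 except a random 10% of genes, which receive a DTU pair —
  one isoform boosted by the fold change in group 1, the other in
  group 2;
* a cohort-based design (`assign_bc`): baseline expression permuted
  within the FSM and NIC category strata, 25% of genes labeled DGE and
  10% DTU with a 4% overlap, fold changes applied as +-sqrt(f) per group
  so each isoform's log-averaged expression is preserved exactly, and
  the DTU pair category mix (two-FSM / FSM+NIC / two-NIC) steered so the
  NIC share among DTU isoforms hits a prescribed rate.

The DTU test is a deliberately simple multinomial likelihood-ratio test
of isoform-proportion homogeneity between groups with a stage-wise
(screen genes, then confirm isoforms) Benjamini-Hochberg correction; it
is plumbing for evaluating assemblies, not a replacement for dedicated
DTU inference engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationDesign",
    "SimTruth",
    "assign_sweep",
    "assign_bc",
    "simulate_counts",
    "dtu_test",
    "evaluate_dtu",
    "bh_adjust",
]


@dataclass
class SimulationDesign:
    """Parameters of the simulation studies (defaults are the sweep's
    central condition)."""

    n_samples_per_group: int = 8
    dtu_fraction: float = 0.10
    dge_fraction: float = 0.25
    both_fraction: float = 0.04
    fold_change: float = 4.0
    nic_rate: float = 0.0
    n_flnc: int = 250_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")
        if self.both_fraction > min(self.dtu_fraction, self.dge_fraction):
            raise ValueError("both_fraction must be <= min(dtu, dge fractions)")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    gene_labels: dict  # gene -> {'dge': bool, 'dtu': bool}
    expression: pd.DataFrame  # isoforms x ['group1', 'group2'] relative expression
    dtu_pairs: dict  # gene -> (isoform_up_in_g1, isoform_up_in_g2)
    categories: dict = field(default_factory=dict)  # isoform -> 'FSM'|'NIC'

    @property
    def dtu_genes(self) -> set:
        return {g for g, lab in self.gene_labels.items() if lab["dtu"]}

    @property
    def dtu_isoforms(self) -> set:
        return {i for pair in self.dtu_pairs.values() for i in pair}


def assign_sweep(genes: dict, design: SimulationDesign) -> SimTruth:
    """Sweep-design labels: relative expression 1 everywhere except a
    random ``dtu_fraction`` of (>= 2-isoform) genes, where a random
    isoform pair gets the fold change in opposite groups.

    ``genes``: gene -> list of isoform ids.
    """
    rng = np.random.default_rng(design.seed)
    gene_ids = sorted(genes)
    eligible = [g for g in gene_ids if len(genes[g]) >= 2]
    n_dtu = int(design.dtu_fraction * len(gene_ids))
    if n_dtu > len(eligible):
        raise ValueError("not enough multi-isoform genes for the requested DTU fraction")
    dtu_genes = set(rng.choice(eligible, size=n_dtu, replace=False).tolist())

    isoforms = [i for g in gene_ids for i in genes[g]]
    expr = pd.DataFrame(1.0, index=isoforms, columns=["group1", "group2"])
    pairs = {}
    for g in sorted(dtu_genes):
        a, b = rng.choice(genes[g], size=2, replace=False).tolist()
        expr.loc[a, "group1"] = design.fold_change
        expr.loc[b, "group2"] = design.fold_change
        pairs[g] = (a, b)
    labels = {g: {"dge": False, "dtu": g in dtu_genes} for g in gene_ids}
    return SimTruth(labels, expr, pairs)


def assign_bc(isoform_table: pd.DataFrame, design: SimulationDesign) -> SimTruth:
    """Cohort-based labels.

    ``isoform_table`` needs columns: gene, category ('FSM'/'NIC'),
    baseline (log-average expression, linear scale > 0); index =
    isoform ids.

    Baselines are permuted within each category stratum; DGE / DTU /
    both label counts are the floors of the design fractions (the 'both'
    set is drawn first, then each label is topped up); group fold
    changes are applied as sqrt(f) up / down so the log-average is
    unchanged; DTU pairs pick the two highest-expression isoforms of
    the category mix steered to ``design.nic_rate``.
    """
    rng = np.random.default_rng(design.seed)
    tab = isoform_table.copy()
    if not {"gene", "category", "baseline"} <= set(tab.columns):
        raise ValueError("isoform_table needs columns gene, category, baseline")

    # (1) permute baseline expression within FSM and within NIC strata
    base = tab["baseline"].astype(float).copy()
    for cat in ("FSM", "NIC"):
        idx = tab.index[tab["category"] == cat]
        base.loc[idx] = rng.permutation(base.loc[idx].to_numpy())
    tab["baseline"] = base

    gene_ids = sorted(tab["gene"].unique())
    n = len(gene_ids)
    n_dge = int(design.dge_fraction * n)
    n_dtu = int(design.dtu_fraction * n)
    n_both = int(design.both_fraction * n)

    by_gene = {g: list(tab.index[tab["gene"] == g]) for g in gene_ids}
    dtu_capable = [g for g in gene_ids if len(by_gene[g]) >= 2]
    if n_dtu > len(dtu_capable):
        raise ValueError("not enough multi-isoform genes for the DTU fraction")

    both = set(rng.choice(dtu_capable, size=min(n_both, n_dtu), replace=False).tolist())
    remaining_dtu = [g for g in dtu_capable if g not in both]
    dtu = both | set(rng.choice(remaining_dtu, size=n_dtu - len(both), replace=False).tolist())
    remaining_dge = [g for g in gene_ids if g not in dtu]
    dge = both | set(rng.choice(remaining_dge, size=n_dge - len(both), replace=False).tolist())

    sf = float(np.sqrt(design.fold_change))
    expr = pd.DataFrame(
        {"group1": tab["baseline"].astype(float), "group2": tab["baseline"].astype(float)}
    )

    # (3) DGE: scale every isoform of the gene by sqrt(f) / 1/sqrt(f)
    for g in sorted(dge):
        up = "group1" if rng.random() < 0.5 else "group2"
        down = "group2" if up == "group1" else "group1"
        expr.loc[by_gene[g], up] *= sf
        expr.loc[by_gene[g], down] /= sf

    # (4) DTU: steer the pair-category tally toward the NIC rate
    n_fsm_avail = {g: int((tab.loc[by_gene[g], "category"] == "FSM").sum()) for g in dtu}
    n_nic_avail = {g: int((tab.loc[by_gene[g], "category"] == "NIC").sum()) for g in dtu}
    max_nic = sum(min(2, n_nic_avail[g]) for g in dtu)
    min_nic = sum(max(0, 2 - n_fsm_avail[g]) for g in dtu)
    target = design.nic_rate * 2 * len(dtu)
    if not (min_nic <= target <= max_nic) and dtu:
        lo, hi = min_nic / (2 * len(dtu)), max_nic / (2 * len(dtu))
        raise ValueError(
            f"nic_rate {design.nic_rate} unattainable; attainable range [{lo:.3f}, {hi:.3f}]"
        )

    pairs = {}
    nic_used = 0
    pairs_done = 0
    shuffled = list(dtu)
    rng.shuffle(shuffled)
    for g in shuffled:
        options = []  # n_nic_in_pair -> (cats)
        if n_fsm_avail[g] >= 2:
            options.append(0)
        if n_fsm_avail[g] >= 1 and n_nic_avail[g] >= 1:
            options.append(1)
        if n_nic_avail[g] >= 2:
            options.append(2)
        # choose the option that keeps the running NIC tally on the
        # proportional track toward the target
        track = target * (pairs_done + 1) / len(dtu)
        opt = min(options, key=lambda o: (abs(nic_used + o - track), abs(o - 2 * design.nic_rate)))
        members = tab.loc[by_gene[g]]
        fsm = members[members["category"] == "FSM"]["baseline"].sort_values(ascending=False)
        nic = members[members["category"] == "NIC"]["baseline"].sort_values(ascending=False)
        if opt == 0:
            pick = list(fsm.index[:2])
        elif opt == 2:
            pick = list(nic.index[:2])
        else:
            pick = [fsm.index[0], nic.index[0]]
        nic_used += opt
        pairs_done += 1
        a, b = pick if rng.random() < 0.5 else pick[::-1]
        expr.loc[a, "group1"] *= sf
        expr.loc[a, "group2"] /= sf
        expr.loc[b, "group1"] /= sf
        expr.loc[b, "group2"] *= sf
        pairs[g] = (a, b)

    labels = {g: {"dge": g in dge, "dtu": g in dtu} for g in gene_ids}
    return SimTruth(labels, expr, pairs, categories=tab["category"].to_dict())


def simulate_counts(
    truth: SimTruth,
    depth: float,
    dispersion: float = 0.05,
    n_samples_per_group: int = 8,
    lengths: dict | None = None,
    seed: int = 0,
) -> tuple:
    """Negative-binomial isoform x sample counts from the truth's
    group-wise relative expression.

    Mean of isoform i in a sample of group g is depth x p_ig where
    p_ig ∝ expression_ig x length_i.  ``dispersion`` d gives variance
    mu + d mu^2 (d = 0 -> Poisson).  Returns (counts DataFrame,
    groups dict sample -> group name).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    isoforms = list(truth.expression.index)
    L = np.array([float((lengths or {}).get(i, 1.0)) for i in isoforms])
    cols, groups = [], {}
    mats = []
    for gi, group in enumerate(("group1", "group2"), 1):
        w = truth.expression[group].to_numpy() * L
        p = w / w.sum()
        mu = depth * p
        for s in range(1, n_samples_per_group + 1):
            name = f"g{gi}_s{s}"
            cols.append(name)
            groups[name] = group
            if dispersion <= 0:
                mats.append(rng.poisson(mu))
            else:
                shape = 1.0 / dispersion
                lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=len(mu)) * mu / shape, 0.0)
                mats.append(rng.poisson(lam))
    counts = pd.DataFrame(np.column_stack(mats), index=isoforms, columns=cols)
    return counts, groups


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _multinomial_ll(x: np.ndarray, p: np.ndarray) -> float:
    mask = x > 0
    return float((x[mask] * np.log(p[mask])).sum())


def dtu_test(counts: pd.DataFrame, gene_map: dict, groups: dict, alpha: float = 0.05):
    """Per-gene multinomial likelihood-ratio test of isoform-proportion
    homogeneity between two groups, with per-isoform follow-up
    (isoform-vs-rest LRT) and stage-wise BH correction.

    Returns (gene_results, isoform_results) DataFrames with p and q
    columns; single-isoform genes are skipped (noted in gene_results
    with p = NaN).
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValueError("exactly two groups required")
    members = {g: [s for s in counts.columns if groups[s] == g] for g in group_names}
    if any(len(m) < 2 for m in members.values()):
        raise ValueError("need >= 2 samples per group")

    genes: dict = {}
    for iso in counts.index:
        genes.setdefault(gene_map[iso], []).append(iso)

    gene_rows, iso_rows = [], []
    for g in sorted(genes):
        isos = genes[g]
        if len(isos) < 2:
            gene_rows.append((g, np.nan, len(isos)))
            continue
        x1 = counts.loc[isos, members[group_names[0]]].to_numpy().sum(axis=1).astype(float)
        x2 = counts.loc[isos, members[group_names[1]]].to_numpy().sum(axis=1).astype(float)
        tot1, tot2 = x1.sum(), x2.sum()
        if tot1 == 0 or tot2 == 0:
            gene_rows.append((g, np.nan, len(isos)))
            continue
        pooled = (x1 + x2) / (tot1 + tot2)
        p1, p2 = x1 / tot1, x2 / tot2
        lrt = 2 * (
            _multinomial_ll(x1, p1) + _multinomial_ll(x2, p2)
            - _multinomial_ll(x1, pooled) - _multinomial_ll(x2, pooled)
        )
        df = len(isos) - 1
        pval = float(stats.chi2.sf(max(lrt, 0.0), df))
        gene_rows.append((g, pval, len(isos)))
        for k, iso in enumerate(isos):
            y1 = np.array([x1[k], tot1 - x1[k]])
            y2 = np.array([x2[k], tot2 - x2[k]])
            pool = (y1 + y2) / (tot1 + tot2)
            q1, q2 = y1 / tot1, y2 / tot2
            l = 2 * (
                _multinomial_ll(y1, q1) + _multinomial_ll(y2, q2)
                - _multinomial_ll(y1, pool) - _multinomial_ll(y2, pool)
            )
            iso_rows.append((iso, g, float(stats.chi2.sf(max(l, 0.0), 1))))

    gene_res = pd.DataFrame(gene_rows, columns=["gene", "p", "n_isoforms"]).set_index("gene")
    tested = gene_res["p"].notna()
    q = np.full(len(gene_res), np.nan)
    q[tested.to_numpy()] = bh_adjust(gene_res.loc[tested, "p"].to_numpy())
    gene_res["q"] = q

    iso_res = pd.DataFrame(iso_rows, columns=["isoform", "gene", "p"]).set_index("isoform")
    screened = set(gene_res.index[(gene_res["q"] < alpha).fillna(False)])
    iso_res["q"] = np.nan
    mask = iso_res["gene"].isin(screened)
    if mask.any():
        iso_res.loc[mask, "q"] = bh_adjust(iso_res.loc[mask, "p"].to_numpy())
    return gene_res, iso_res


def evaluate_dtu(called_isoforms, truth: SimTruth):
    """Precision / recall of a called DTU-isoform set against the truth
    pairs.  Empty call set: precision NaN, recall 0."""
    called = set(called_isoforms)
    true = truth.dtu_isoforms
    tp = called & true
    fp = called - true
    fn = true - called
    precision = float("nan") if not called else len(tp) / len(called)
    recall = 0.0 if not true else len(tp) / len(true)
    if not true:
        recall = float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }
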