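"""Cross-cohort isoform statistics: two-tailed Fisher's exact test,
common / unique / subtype-specific categorization of the detection
matrix, and fold-change ranking of subtype-specific isoforms.

The Fisher test is computed by exact integer enumeration of the
hypergeometric distribution with fixed margins: the two-sided p-value is
the sum of point probabilities not exceeding the observed table's.
Integer arithmetic makes the tie comparison exact, so no floating-point
slack is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, log2

import numpy as np
import pandas as pd

__all__ = [
    "SpecificityCall",
    "fisher_two_tailed",
    "categorize_isoforms",
    "rank_by_fold_change",
]


@dataclass
class SpecificityCall:
    category: str  # 'common' | 'unique' | 'subtype_specific' | 'other'
    group: str | None = None  # set for subtype_specific
    fisher_p: float = 1.0


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities <= the observed table's
    probability (exact integer tie comparison).  Degenerate margins give
    p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = weights[a - lo]
    num = sum(w for w in weights if w <= obs)
    return float(Fraction(num, comb(n, c1)))


def categorize_isoforms(
    detection: pd.DataFrame,
    groups: dict,
    alpha: float = 0.05,
    min_detected: dict | None = None,
) -> dict:
    """Categorize each isoform of a boolean isoform x sample detection
    matrix into common / unique / subtype_specific / other.

    * common: detected in more than half the samples of BOTH groups;
    * unique: detected in exactly one sample overall;
    * subtype_specific: all detections in one group, and the detected
      count differs significantly between groups (two-tailed Fisher,
      p < alpha); ``min_detected`` (group -> count) optionally replaces
      the Fisher criterion with an explicit threshold (detections
      strictly greater than the given count);
    * other: everything else.
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValueError(f"exactly two groups required, got {group_names}")
    g1, g2 = group_names
    members = {g: [s for s in detection.columns if groups[s] == g] for g in group_names}
    n1, n2 = len(members[g1]), len(members[g2])
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need >= 1 sample")

    calls = {}
    for iso in detection.index:
        row = detection.loc[iso]
        k1 = int(row[members[g1]].sum())
        k2 = int(row[members[g2]].sum())
        if k1 > n1 / 2 and k2 > n2 / 2:
            calls[iso] = SpecificityCall("common")
            continue
        if k1 + k2 == 1:
            calls[iso] = SpecificityCall("unique")
            continue
        if (k1 > 0) != (k2 > 0):
            g, k, ng, n_other = (g1, k1, n1, n2) if k1 > 0 else (g2, k2, n2, n1)
            p = fisher_two_tailed(k, ng - k, 0, n_other)
            if min_detected is not None:
                significant = k > min_detected.get(g, 0)
            else:
                significant = p < alpha
            if significant:
                calls[iso] = SpecificityCall("subtype_specific", group=g, fisher_p=p)
                continue
            calls[iso] = SpecificityCall("other", fisher_p=p)
            continue
        calls[iso] = SpecificityCall("other")
    return calls


def rank_by_fold_change(
    tpm: pd.DataFrame,
    calls: dict,
    groups: dict,
    top_n: int = 100,
    pseudocount: float = 0.01,
    clip: float = 10.0,
) -> pd.DataFrame:
    """Rank subtype-specific isoforms by |log2 fold change| of mean TPM
    between their own group and the other, with a pseudocount against
    zero means; reported values are clipped to [-clip, clip].

    Returns a DataFrame (isoform, group, log2fc) of the top ``top_n``.
    """
    if (tpm.values < 0).any():
        raise ValueError("TPM must be non-negative")
    group_names = sorted(set(groups.values()))
    members = {g: [s for s in tpm.columns if groups[s] == g] for g in group_names}
    rows = []
    for iso, call in calls.items():
        if call.category != "subtype_specific" or iso not in tpm.index:
            continue
        own = call.group
        other = next(g for g in group_names if g != own)
        m_own = float(tpm.loc[iso, members[own]].mean())
        m_other = float(tpm.loc[iso, members[other]].mean())
        fc = log2((m_own + pseudocount) / (m_other + pseudocount))
        rows.append((iso, own, fc))
    rows.sort(key=lambda r: (-abs(r[2]), r[0]))
    rows = rows[:top_n]
    return pd.DataFrame(
        [(i, g, float(np.clip(fc, -clip, clip))) for i, g, fc in rows],
        columns=["isoform", "group", "log2fc"],
    )
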