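"""Shared statistical helpers: BH adjustment and one-sided rank-sum tests."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values; NaNs are passed through and
    excluded from the correction denominator."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def rank_sum_one_sided(
    query: np.ndarray, rest: np.ndarray, alternative: str = "greater"
) -> float:
    """One-sided Wilcoxon rank-sum (Mann–Whitney U) p-value.

    Exact null enumeration of all rank splits for group sizes <= 8 (ties
    handled with average ranks); normal approximation with tie and
    continuity correction otherwise.
    """
    from itertools import combinations

    query = np.asarray(query, dtype=float)
    rest = np.asarray(rest, dtype=float)
    pooled = np.concatenate([query, rest])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(query) <= 8 and len(rest) <= 8:
        ranks = stats.rankdata(pooled)
        obs = ranks[: len(query)].sum()
        total = hits = 0
        for combo in combinations(range(len(pooled)), len(query)):
            s = ranks[list(combo)].sum()
            total += 1
            if alternative == "greater":
                hits += s >= obs - 1e-9
            else:
                hits += s <= obs + 1e-9
        return hits / total
    return float(
        stats.mannwhitneyu(query, rest, alternative=alternative, method="asymptotic").pvalue
    )
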