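"""Shared statistical primitives: multiplicity correction and rank tests.

Two-sample location tests on intensity data use Student's t (pooled
variance by default, Welch optional) via scipy. Rank-based comparisons of
single-cell enrichment values use the Wilcoxon rank-sum and Kruskal-Wallis
tests; for small samples the p-values are computed exactly over the full
permutation distribution rather than by normal / chi-square approximation.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "adjust_pvalues",
    "two_sample_t",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
]

#: Enumerate the exact permutation null only while the number of
#: arrangements stays below this bound; beyond it fall back to the
#: large-sample approximation.
MAX_EXACT_ARRANGEMENTS = 200_000


def adjust_pvalues(pvalues: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Adjust p-values for multiple testing.

    ``bonferroni`` multiplies each p by the family size (capped at 1);
    any other method name supported by
    :func:`statsmodels.stats.multitest.multipletests` (e.g. ``fdr_bh``)
    is passed through.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method=method)[1]


def two_sample_t(x: np.ndarray, y: np.ndarray, axis: int = -1,
                 equal_var: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t-test; returns (statistic, two-sided p).

    ``equal_var=True`` is the classical Student test with pooled variance;
    ``False`` gives Welch's test. Vectorised over ``axis``.
    """
    res = sps.ttest_ind(x, y, axis=axis, equal_var=equal_var)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # Identical constant samples give 0/0 -> nan; no evidence of change.
    p = np.where(np.isnan(p), 1.0, p)
    return stat, p


# ---------------------------------------------------------------------------
# Rank tests with exact small-sample null distributions
# ---------------------------------------------------------------------------


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray,
                      alternative: str) -> float:
    """Exact rank-sum p by enumerating all assignments of the pooled values
    to the first group. Handles ties through midranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, m = len(x), len(y)
    obs = ranks[:n].sum()
    mean = n * (n + m + 1) / 2.0
    count_ge = 0
    count_le = 0
    count_extreme = 0
    total = 0
    eps = 1e-9
    for idx in combinations(range(n + m), n):
        w = ranks[list(idx)].sum()
        total += 1
        if w >= obs - eps:
            count_ge += 1
        if w <= obs + eps:
            count_le += 1
        if abs(w - mean) >= abs(obs - mean) - eps:
            count_extreme += 1
    if alternative == "greater":
        return count_ge / total
    if alternative == "less":
        return count_le / total
    return count_extreme / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> dict:
    """Wilcoxon rank-sum (Mann-Whitney) test for two independent samples.

    Uses the exact null distribution when the number of group assignments
    is small enough (always the case for the per-treatment cell counts the
    pipeline compares), otherwise the tie-corrected normal approximation.
    Returns ``{statistic, p_value, method}`` where ``statistic`` is the
    Mann-Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n_arrangements = math.comb(len(x) + len(y), len(x))
    u = sps.mannwhitneyu(x, y, alternative=alternative,
                         method="asymptotic").statistic
    if n_arrangements <= MAX_EXACT_ARRANGEMENTS:
        p = _rank_sum_exact_p(x, y, alternative)
        method = "exact"
    else:
        p = sps.mannwhitneyu(x, y, alternative=alternative,
                             method="asymptotic").pvalue
        method = "normal-approximation"
    return {"statistic": float(u), "p_value": float(p), "method": method}


def _kw_statistic(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction, computed from pooled ranks."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / float(n ** 3 - n)
    if tie == 0:
        return 0.0  # every observation identical
    return h / tie


def _multiset_splits(n_total: int, sizes: Sequence[int]):
    """Yield index tuples splitting range(n_total) into groups of the given
    sizes (order of groups fixed, order within groups ignored)."""
    indices = list(range(n_total))

    def rec(remaining: list[int], sizes_left: Sequence[int]):
        if len(sizes_left) == 1:
            yield (tuple(remaining),)
            return
        k = sizes_left[0]
        for chosen in combinations(remaining, k):
            rest = [i for i in remaining if i not in set(chosen)]
            for tail in rec(rest, sizes_left[1:]):
                yield (chosen,) + tail

    yield from rec(indices, sizes)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> dict:
    """Kruskal-Wallis H test across >= 2 independent samples.

    For small total sample sizes the p-value is the exact probability,
    under random assignment of the pooled observations to groups of the
    observed sizes, of an H at least as large as observed; otherwise the
    chi-square approximation is used. Returns
    ``{statistic, p_value, method}``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) == 0 for a in arrs):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        # Every observation identical: no evidence against the null.
        return {"statistic": 0.0, "p_value": 1.0, "method": "degenerate-ties"}
    sizes = [len(a) for a in arrs]
    n = len(pooled)
    n_arrangements = math.factorial(n)
    for k in sizes:
        n_arrangements //= math.factorial(k)
    obs = _kw_statistic(arrs)
    if n_arrangements <= MAX_EXACT_ARRANGEMENTS:
        count = 0
        total = 0
        eps = 1e-9
        for split in _multiset_splits(n, sizes):
            perm_groups = [pooled[list(idx)] for idx in split]
            if _kw_statistic(perm_groups) >= obs - eps:
                count += 1
            total += 1
        return {"statistic": float(obs), "p_value": count / total,
                "method": "exact"}
    stat, p = sps.kruskal(*arrs)
    return {"statistic": float(stat), "p_value": float(p),
            "method": "chi-square-approximation"}
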