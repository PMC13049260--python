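"""Nonparametric repeated-measures statistics: Friedman omnibus test with an
exact small-sample permutation mode, pairwise Wilcoxon signed-rank tests
(Pratt zero handling, exact distribution for n <= 25) and Bonferroni
adjustment."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.stats import chi2, norm, rankdata


def _midranks(row: np.ndarray) -> np.ndarray:
    return rankdata(row)


def friedman_statistic(table: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square statistic.

    ``table`` is (n_subjects, n_methods); ranks are midranks within each
    subject.  Reduces to the classical 12/(nk(k+1)) formula without ties.
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    ranks = np.apply_along_axis(_midranks, 1, table)
    colsum = ranks.sum(axis=0)
    num = (k - 1) * float(np.sum((colsum - n * (k + 1) / 2.0) ** 2))
    den = float(np.sum(ranks**2)) - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:  # all scores identical in every subject
        return 0.0
    return num / den


def _exact_friedman_pvalue(table: np.ndarray, observed: float) -> float:
    """Exact permutation p-value by DP over within-subject rank permutations."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    ranks = np.apply_along_axis(_midranks, 1, table)
    iranks = np.round(2 * ranks).astype(int)  # integer midranks (x2)
    sum_r2 = float(np.sum(ranks**2))
    den = sum_r2 - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:
        return 1.0

    dist = {tuple([0] * k): 1.0}
    for i in range(n):
        perms = set(permutations(iranks[i]))
        new: dict = {}
        w = 1.0 / len(perms)
        for state, prob in dist.items():
            for p in perms:
                key = tuple(s + r for s, r in zip(state, p))
                new[key] = new.get(key, 0.0) + prob * w
        dist = new

    p = 0.0
    for state, prob in dist.items():
        colsum = np.asarray(state) / 2.0
        stat = (k - 1) * float(np.sum((colsum - n * (k + 1) / 2.0) ** 2)) / den
        if stat >= observed - 1e-12:
            p += prob
    return min(p, 1.0)


def friedman_test(table: np.ndarray, method: str = "auto") -> dict:
    """Friedman test on a (n_subjects, n_methods) table.

    ``method``: 'exact' (permutation null), 'asymptotic' (chi-square with
    k-1 dof) or 'auto' (exact below 5 subjects, asymptotic otherwise).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need a (n_subjects, n_methods>=2) table")
    n, k = table.shape
    stat = friedman_statistic(table)
    if method == "auto":
        method = "exact" if n < 5 else "asymptotic"
    if method == "exact":
        p = _exact_friedman_pvalue(table, stat)
    elif method == "asymptotic":
        p = float(chi2.sf(stat, k - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    if stat == 0.0:
        p = 1.0
    return {"statistic": stat, "pvalue": p, "method": method, "n": n, "k": k}


# ----------------------------------------------------------------------------
# Wilcoxon signed rank (Pratt)
# ----------------------------------------------------------------------------


def _signed_rank_pratt(d: np.ndarray) -> tuple:
    """Pratt ranking: rank |d| including zeros, drop zero ranks afterwards.

    Returns (w_plus, nonzero_ranks, n_zero) with ranks as midranks.
    """
    d = np.asarray(d, dtype=float)
    ranks = rankdata(np.abs(d))
    nz = d != 0
    w_plus = float(ranks[(d > 0)].sum())
    return w_plus, ranks[nz], int(np.sum(~nz))


def _exact_wplus_distribution(ranks: np.ndarray) -> tuple:
    """Null pmf of W+ over sign flips of the given (mid)ranks, by DP.

    Ranks are doubled to integers; returns (support_values, pmf).
    """
    ir = np.round(2 * np.asarray(ranks)).astype(int)
    total = int(ir.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ir:
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = 0.5 * nxt
    support = np.arange(total + 1) / 2.0
    return support, pmf


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray | None = None, method: str = "auto"
) -> dict:
    """Two-sided Wilcoxon signed-rank test with Pratt zero handling.

    Exact null distribution (dynamic programming over midranks, valid with
    ties) for n <= 25 differences; normal approximation with tie and zero
    corrections above.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    n = d.size
    if n < 1:
        raise ValueError("empty sample")
    w_plus, nz_ranks, n_zero = _signed_rank_pratt(d)
    if nz_ranks.size == 0:
        return {"statistic": w_plus, "pvalue": 1.0, "method": "degenerate", "n": n}
    if method == "auto":
        method = "exact" if n <= 25 else "approx"
    if method == "exact":
        # zero ranks contribute nothing to W+ but shift the ranking (Pratt)
        support, pmf = _exact_wplus_distribution(nz_ranks)
        cdf = np.cumsum(pmf)
        idx = int(np.searchsorted(support, w_plus - 1e-9))
        p_le = float(cdf[min(idx, len(cdf) - 1)]) if w_plus >= support[0] else 0.0
        # recompute inclusively
        p_le = float(pmf[support <= w_plus + 1e-9].sum())
        p_ge = float(pmf[support >= w_plus - 1e-9].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif method == "approx":
        ranks_all = rankdata(np.abs(d))
        mu = (n * (n + 1) / 4.0) - (n_zero * (n_zero + 1) / 4.0)
        var = (
            n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)
        ) / 24.0
        _, counts = np.unique(ranks_all, return_counts=True)
        var -= float(np.sum(counts**3 - counts)) / 48.0
        if var <= 0:
            return {"statistic": w_plus, "pvalue": 1.0, "method": method, "n": n}
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
        p = min(1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": w_plus, "pvalue": p, "method": method, "n": n}


def bonferroni(p: float, m: int) -> float:
    """Adjusted p = min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)
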