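"""Shared statistical primitives: rank-sum tests, BH adjustment, correlation.

The Wilcoxon rank-sum test switches between an exact permutation null
(both groups <= 6 observations) and the normal approximation with tie and
continuity correction.  A fully vectorized approximate path is used for the
genome-wide scans.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 6  # per-group size at or below which the exact null is enumerated


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_exact(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Uses midranks, so ties are handled; the two-sided p is twice the
    smaller tail of the permutation distribution of the rank sum (capped
    at 1), which reduces to the classical exact Wilcoxon p when there are
    no ties.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    lo = hi = 0
    total = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def rank_sum_normal(x, y) -> float:
    """Two-sided rank-sum p via the normal approximation (tie + continuity corrected)."""
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p; exact when both groups are small."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return rank_sum_exact(x, y)
    return rank_sum_normal(x, y)


def rank_sum_rows(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p per row of ``values``.

    Parameters
    ----------
    values
        features x samples array.
    in_group
        boolean sample mask (group A = True vs rest).

    Rows with zero spread get p = 1.  Small-sample rows (both groups <= 6)
    fall back to the exact test.
    """
    values = np.asarray(values, float)
    in_group = np.asarray(in_group, bool)
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        return np.array([rank_sum_test(row[in_group], row[~in_group])
                         for row in values])
    ranks = scipy.stats.rankdata(values, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction: sum of (t^3 - t) over tied groups, per row
    tie_term = np.zeros(values.shape[0])
    srt = np.sort(values, axis=1)
    for i, row in enumerate(srt):
        _, counts = np.unique(row, return_counts=True)
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(values.shape[0])
    ok = sigma2 > 0
    z = (np.abs(u[ok] - mu) - 0.5) / np.sqrt(sigma2[ok])
    z = np.maximum(z, 0.0)
    p[ok] = 2.0 * scipy.stats.norm.sf(z)
    return np.minimum(p, 1.0)


def log2_fold_change(mean_a: np.ndarray, mean_b: np.ndarray,
                     pseudocount: float = 1e-9) -> np.ndarray:
    """log2((mean_a + c) / (mean_b + c)) with a zero-safe pseudocount."""
    return np.log2((np.asarray(mean_a, float) + pseudocount)
                   / (np.asarray(mean_b, float) + pseudocount))


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided t-based p; zero variance is an error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
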