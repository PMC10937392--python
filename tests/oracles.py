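"""Independent literal-definition oracles.

Each function re-derives a quantity by the most direct route available —
nested loops, exhaustive enumeration, closed forms — sharing no code with
the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np


def ssgsea_oracle(values: np.ndarray, gene_ids: list[str],
                  set_genes: list[str], alpha: float) -> float:
    """Direct nested-loop ssGSEA enrichment score for one sample.

    Ranks computed by pairwise comparison (average rank under ties); walk
    order by expression descending with gene-id tie-break; the running sum
    evaluated position by position.
    """
    n = len(values)
    # ascending average rank by counting pairwise comparisons
    r = np.zeros(n)
    for i in range(n):
        less = sum(1 for j in range(n) if values[j] < values[i])
        equal = sum(1 for j in range(n) if values[j] == values[i])
        r[i] = less + (equal + 1) / 2.0
    # weight r_i = N - rank_desc + 1 where rank_desc = N + 1 - rank_asc
    weight = r  # algebraically equals the ascending average rank
    order = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    in_set = [gene_ids[i] in set_genes for i in range(n)]
    denom_in = sum(weight[i] ** alpha for i in range(n) if in_set[i])
    n_out = n - sum(in_set)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for pos in order:
        if in_set[pos]:
            cum_in += weight[pos] ** alpha
        else:
            cum_out += 1
        es += cum_in / denom_in - cum_out / n_out
    return es


def ranksum_p_oracle(x, y) -> float:
    """Exhaustive two-sided rank-sum p via the Mann-Whitney U count statistic.

    U is computed by direct pairwise comparison (ties count 1/2); the null
    enumerates every assignment of the pooled values into the two groups,
    and the two-sided p doubles the smaller tail (capped at 1).
    """
    def u_stat(a, b):
        return sum(1.0 if ai > bi else 0.5 if ai == bi else 0.0
                   for ai in a for bi in b)

    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = u_stat(x, y)
    lo = hi = total = 0
    for idx in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(a, b)
        total += 1
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p by summing hypergeometric probabilities.

    Enumerates every table with the observed margins and at least ``a``
    in the top-left cell.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(n, col1)
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        if col1 - x > n - row1:
            continue
        p += math.comb(row1, x) * math.comb(n - row1, col1 - x) / denom
    return p


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Literal BH step-up: q_(i) = min_{j >= i} min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(1.0, running)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def logrank_oracle(times, events, groups) -> float:
    """Two-group log-rank chi-square by direct O-E / V summation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def km_oracle(times, events) -> list[tuple[float, float]]:
    """Product-limit curve by direct multiplication at each event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    curve = []
    for t in np.unique(times[events == 1]):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= (n - d) / n
        curve.append((float(t), s))
    return curve


def ntp_exhaustive_oracle(x: np.ndarray, templates: np.ndarray) -> tuple[int, float]:
    """Exhaustive-permutation NTP for a tiny universe.

    Returns (winning template index, exact p) where the null enumerates all
    G! gene relabelings and re-classifies each (minimum correlation
    distance over templates).
    """
    def corr(u, v):
        u = np.asarray(u, float) - np.mean(u)
        v = np.asarray(v, float) - np.mean(v)
        return float(u @ v / np.sqrt((u @ u) * (v @ v)))

    d = [1.0 - corr(x, t) for t in templates]
    d_obs = min(d)
    win = int(np.argmin(d))
    count = 0
    total = 0
    for perm in permutations(range(len(x))):
        xp = x[list(perm)]
        dp = min(1.0 - corr(xp, t) for t in templates)
        total += 1
        if dp <= d_obs + 1e-12:
            count += 1
    return win, count / total
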