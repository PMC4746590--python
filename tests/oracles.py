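"""Independent brute-force oracles used to cross-check the statistical kernels.

Everything here is deliberately naive — enumeration, closed forms and
O(n^2) scans — and shares no code path with the package implementation.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def ranksum_pvalue_exact(a, b) -> float:
    """Two-sided rank-sum p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = np.asarray(a + b, dtype=float)
    n_a = len(a)
    ranks = _midranks(pooled)
    obs = sum(ranks[: n_a])
    stats = []
    for idx in combinations(range(len(pooled)), n_a):
        stats.append(sum(ranks[i] for i in idx))
    stats = np.asarray(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)
    return float(min(p, 1.0))


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def fisher_pvalue_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration (point-probability)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = point(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = point(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def bh_qvalues_naive(pvalues) -> np.ndarray:
    """O(n^2) Benjamini-Hochberg: q_i = min over p_(j) >= p_i of p_(j)*n/rank(j)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    q = np.empty(n)
    for i in range(n):
        candidates = [
            p[j] * n / ranks[j]
            for j in range(n)
            if p[j] >= p[i] - 1e-15
        ]
        q[i] = min(1.0, min(candidates))
    return q


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) by direct pmf summation."""
    return sum(
        math.comb(n, x) * p0**x * (1 - p0) ** (n - x) for x in range(k, n + 1)
    )


def median_subset_pvalues(scores, m: int, observed: float):
    """Exact permutation p values for a median-of-subset statistic."""
    scores = np.asarray(scores, dtype=float)
    le = ge = total = 0
    for idx in combinations(range(len(scores)), m):
        med = np.median(scores[list(idx)])
        total += 1
        if med <= observed:
            le += 1
        if med >= observed:
            ge += 1
    return le / total, ge / total


def pearson_fisher_z(x, y):
    """Pearson r and Fisher-z two-sided p recomputed from first principles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))
    n = len(x)
    if abs(r) >= 1.0:
        return r, 0.0
    z = math.atanh(r) * math.sqrt(n - 3)
    p = math.erfc(abs(z) / math.sqrt(2))
    return r, min(p, 1.0)
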