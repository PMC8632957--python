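"""Independent brute-force oracles used to freeze expected values.

Everything here is implemented from first principles (enumeration, dynamic
programming, closed forms) without touching the code paths under test.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from scipy.special import gammaincc


@lru_cache(maxsize=None)
def mw_u_counts(m: int, n: int) -> tuple[int, ...]:
    """Counts of the exact Mann-Whitney U null distribution for sizes (m, n).

    f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u), the standard partition
    recursion over the number of arrangements giving each U value.
    """
    if m == 0 or n == 0:
        return (1,)
    a = mw_u_counts(m - 1, n)  # length (m-1)*n + 1
    b = mw_u_counts(m, n - 1)  # length m*(n-1) + 1
    out = [0] * (m * n + 1)
    for u in range(m * n + 1):
        if u - n >= 0 and u - n < len(a):
            out[u] += a[u - n]
        if u < len(b):
            out[u] += b[u]
    return tuple(out)


def exact_mw_pvalue(x, y) -> float:
    """Two-sided exact Mann-Whitney p for tie-free samples.

    p = min(1, 2 * min(P(U <= u), P(U >= u))) from the enumerated null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = int(sum(1 for xi in x for yj in y if xi > yj))
    counts = mw_u_counts(len(x), len(y))
    total = sum(counts)
    lower = sum(counts[: u + 1]) / total
    upper = sum(counts[u:]) / total
    return min(1.0, 2.0 * min(lower, upper))


def permutation_mw_best_division(values_sorted, divisions) -> int | None:
    """Argmin division by exhaustive permutation Mann-Whitney (handles ties).

    For each left size k, the permutation p is the fraction of all C(n, k)
    label assignments whose |U - mn/2| is at least the observed one (U with
    0.5 credit for ties).  Returns the chosen left size using the balanced /
    smaller-left tie-break, or None if every p >= 0.05.
    """
    vals = list(values_sorted)
    n = len(vals)

    def u_stat(left_idx: frozenset) -> float:
        left = [vals[i] for i in left_idx]
        right = [vals[i] for i in range(n) if i not in left_idx]
        u = 0.0
        for a in left:
            for b in right:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    best = None
    for k in divisions:
        mn = k * (n - k)
        obs = abs(u_stat(frozenset(range(k))) - mn / 2)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), k):
            total += 1
            if abs(u_stat(frozenset(combo)) - mn / 2) >= obs - 1e-12:
                count += 1
        p = count / total
        key = (p, abs(n - 2 * k), k)
        if best is None or key < best:
            best = key
    p, _, k = best
    return None if p >= 0.05 else k


def exhaustive_best_division(values_sorted, alpha: float = 0.05) -> int | None:
    """Argmin left size over all admissible divisions by exact (tie-free)
    Mann-Whitney; None when the minimum p is >= alpha."""
    vals = np.asarray(values_sorted, dtype=float)
    n = len(vals)
    if n < 6:
        return None
    best = None
    for k in range(3, n - 2):
        p = exact_mw_pvalue(vals[:k], vals[k:])
        key = (p, abs(n - 2 * k), k)
        if best is None or key < best:
            best = key
    p, _, k = best
    return None if p >= alpha else k


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by enumerating the hypergeometric support."""
    (a, b), (c, d) = table
    row1, col1, N = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - N)
    hi = min(row1, col1)
    denom = math.comb(N, col1)

    def prob(x: int) -> float:
        return math.comb(row1, x) * math.comb(N - row1, col1 - x) / denom

    p_obs = prob(a)
    return min(1.0, sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9)))


def fisher_greater(table) -> float:
    """One-sided (greater) Fisher exact p by enumeration."""
    (a, b), (c, d) = table
    row1, col1, N = a + b, a + c, a + b + c + d
    hi = min(row1, col1)
    denom = math.comb(N, col1)
    return min(
        1.0,
        sum(
            math.comb(row1, x) * math.comb(N - row1, col1 - x) / denom
            for x in range(a, hi + 1)
        ),
    )


def hypergeom_upper(x: int, M: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(M, K, n), by enumeration."""
    denom = math.comb(M, n)
    return min(
        1.0,
        sum(
            math.comb(K, i) * math.comb(M - K, n - i) / denom
            for i in range(max(x, max(0, n - (M - K))), min(K, n) + 1)
        ),
    )


def chi2_pvalue(table) -> float:
    """Pearson chi-squared p from the textbook statistic and the regularised
    upper incomplete gamma function (independent of chi2_contingency)."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(gammaincc(df / 2.0, stat / 2.0))


def bh_by_hand(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up written directly from the definition."""
    p = list(pvalues)
    n = len(p)
    indexed = sorted(range(n), key=lambda i: p[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = indexed[rank - 1]
        running = min(running, p[i] * n / rank)
        adjusted[i] = running
    return adjusted
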