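"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written on a different code path from the
package: pure-Python loops, combinatorial enumeration, numeric integration
and recursive dynamic programming. Slow but simple.
"""

from __future__ import annotations

import math
from functools import lru_cache

from scipy.integrate import quad


def pearson_brute(x, y) -> float:
    """Pearson R by the direct covariance-over-sd formula, pure Python."""
    n = len(x)
    assert n == len(y) and n >= 3
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        dx, dy = xi - mx, yi - my
        sxy += dx * dy
        sxx += dx * dx
        syy += dy * dy
    return sxy / math.sqrt(sxx * syy)


def t_density(x: float, df: int) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1.0 + x * x / df) ** (-(df + 1) / 2)


def pearson_pvalue_integral(r: float, n: int) -> float:
    """Two-sided Pearson p by numeric integration of the t density."""
    if abs(r) >= 1.0:
        return 0.0
    df = n - 2
    t = abs(r) * math.sqrt(df / (1.0 - r * r))
    tail, _ = quad(t_density, t, math.inf, args=(df,))
    return min(1.0, 2.0 * tail)


def critical_r_bisect(n: int, alpha: float, tol: float = 1e-13) -> float:
    """Invert pearson_pvalue_integral by bisection on |r|."""
    lo, hi = 0.0, 1.0 - 1e-15
    for _ in range(200):
        mid = (lo + hi) / 2
        if pearson_pvalue_integral(mid, n) > alpha:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by explicit combinatorial counting."""
    total = math.comb(N, n)
    count = 0
    for kk in range(k, min(K, n) + 1):
        count += math.comb(K, kk) * math.comb(N - K, n - kk)
    return count / total


def hypergeom_cdf_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X <= k) by explicit combinatorial counting."""
    total = math.comb(N, n)
    count = 0
    lo = max(0, n - (N - K))
    for kk in range(lo, min(k, K, n) + 1):
        count += math.comb(K, kk) * math.comb(N - K, n - kk)
    return count / total


def bh_stepup_brute(p_values) -> list[float]:
    """BH q-values straight from the definition: q_i is the smallest
    p_(j) * m / j over all j whose sorted p is >= p_i, capped at 1."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(indexed, start=1):
        best = min(
            p_values[j] * m / (jr + 1)
            for jr, j in enumerate(indexed)
            if jr + 1 >= rank_pos
        )
        q[i] = min(1.0, best)
    return q


IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _char_match(seq_char: str, code: str) -> bool:
    return bool(set(IUPAC_SETS.get(seq_char, "")) & set(IUPAC_SETS[code]))


def edit_distance_recursive(window: str, consensus: str) -> int:
    """Levenshtein distance with degenerate matching, by memoized recursion."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        sub = d(i - 1, j - 1) + (0 if _char_match(window[i - 1], consensus[j - 1]) else 1)
        return min(sub, d(i - 1, j) + 1, d(i, j - 1) + 1)

    return d(len(window), len(consensus))


def naive_degenerate_matches(seq: str, consensus: str) -> list[int]:
    """0-based start positions of exact (edit distance 0) degenerate matches."""
    m = len(consensus)
    out = []
    for start in range(len(seq) - m + 1):
        if all(_char_match(seq[start + j], consensus[j]) for j in range(m)):
            out.append(start)
    return out


def enumerate_interval(start: int, end: int) -> list[int]:
    """All no-zero TSS coordinates from start to end inclusive."""
    assert start != 0 and end != 0
    out = []
    c = start
    while True:
        out.append(c)
        if c == end:
            break
        c += 1
        if c == 0:
            c = 1
    return out
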