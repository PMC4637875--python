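"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the KS statistic is
a double-loop ECDF scan, the exact KS p is a from-first-principles
enumeration with that brute statistic, and the hypergeometric tail is
exact integer arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def brute_ks_statistic(x, y) -> float:
    """Max |ECDF_x(t) - ECDF_y(t)| scanned over every pooled value."""
    x, y = list(x), list(y)
    best = 0.0
    for t in x + y:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def enumerate_ks_pvalue(x, y) -> Fraction:
    """Exact two-sided KS p: fraction of all C(n1+n2, n1) label splits of
    the pooled multiset whose brute-force D is >= the observed D."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    d_obs = brute_ks_statistic(x, y)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        chosen = set(combo)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        if brute_ks_statistic(xs, ys) >= d_obs - 1e-12:
            hits += 1
        total += 1
    return Fraction(hits, total)


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(max(k, 0, n + K - N), min(K, n) + 1))
    return Fraction(num, comb(N, n))
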