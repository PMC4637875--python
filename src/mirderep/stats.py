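"""Core statistical machinery: two-sample KS, one-sided Fisher exact,
Pearson correlation, and Benjamini-Hochberg q-values.

These four primitives carry the inferential weight of the whole pipeline
(derepression CDF shifts, signature overlaps, knockout/wild-type miRNA
concordance, DE thresholds), so they are implemented here explicitly
rather than delegated, with exact modes and log-space arithmetic where
precision matters. Results carry enough provenance (sample sizes, method
used) to be serialized into run reports.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "KSResult",
    "ContingencyCounts",
    "ks_two_sample",
    "fisher_one_sided",
    "pearson_r",
    "bh_qvalues",
]

# totals up to this size get full-enumeration exact KS p-values in auto mode;
# C(16, 8) = 12,870 splits is instant, beyond that asymptotics take over
_EXACT_KS_MAX_TOTAL = 16


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov test result.

    D is the maximum vertical distance between the two empirical CDFs;
    p is two-sided, from either the asymptotic Kolmogorov distribution
    (with the Stephens small-sample correction) or full enumeration of
    label assignments (tie-aware by construction).
    """

    D: float
    p: float
    n1: int
    n2: int
    method: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ContingencyCounts:
    """Overlap table for a one-sided (upper-tail) Fisher exact test.

    k: observed overlap, K: signature size, n: query-set size,
    N: universe size.
    """

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"k={self.k} must lie in [0, min(K, n)]")
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError("require K <= N and n <= N with all counts >= 0")
        if self.N <= 0:
            raise ValueError("universe must be non-empty")


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Max |ECDF_x - ECDF_y| evaluated at every pooled distinct value."""
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.union1d(xs, ys)
    cdf_x = np.searchsorted(xs, grid, side="right") / xs.size
    cdf_y = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _kolmogorov_sf(lam: float) -> float:
    """Survival function of the Kolmogorov distribution, Q(lambda).

    Uses the alternating series 2*sum_j (-1)^(j-1) exp(-2 j^2 lam^2) for
    large lam and the theta-function form for small lam, where the
    alternating series converges slowly.
    """
    if lam <= 0:
        return 1.0
    if lam < 1.0:
        # CDF = sqrt(2*pi)/lam * sum_j exp(-(2j-1)^2 pi^2 / (8 lam^2))
        t = math.pi**2 / (8.0 * lam**2)
        cdf = 0.0
        for j in range(1, 20):
            term = math.exp(-((2 * j - 1) ** 2) * t)
            cdf += term
            if term < 1e-18:
                break
        cdf *= math.sqrt(2.0 * math.pi) / lam
        return min(max(1.0 - cdf, 0.0), 1.0)
    s = 0.0
    for j in range(1, 101):
        term = 2.0 * (-1.0) ** (j - 1) * math.exp(-2.0 * j * j * lam * lam)
        s += term
        if abs(term) < 1e-18:
            break
    return min(max(s, 0.0), 1.0)


def _ks_asymptotic_p(d: float, n1: int, n2: int) -> float:
    # classic Smirnov limit, lambda = sqrt(ne) * D. Finite-sample lambda
    # corrections (e.g. the +0.12+0.11/sqrt(ne) adjustment) approximate
    # the mid-p of the discrete null distribution; the uncorrected limit
    # tracks the inclusive tail P(D >= d) that exact/permutation
    # p-values use, which is what this function approximates.
    ne = n1 * n2 / (n1 + n2)
    return _kolmogorov_sf(math.sqrt(ne) * d)


def _ks_exact_p(x: np.ndarray, y: np.ndarray, d_obs: float) -> float:
    """Exact p by enumerating all C(n1+n2, n1) label assignments of the
    pooled sample. Handles ties correctly because the pooled multiset is
    re-split as observed."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    total = pooled.size
    n_ge = 0
    n_splits = 0
    idx = np.arange(total)
    for combo in itertools.combinations(range(total), n1):
        mask = np.zeros(total, dtype=bool)
        mask[list(combo)] = True
        d = _ks_statistic(pooled[mask], pooled[idx[~mask]])
        if d >= d_obs - 1e-12:
            n_ge += 1
        n_splits += 1
    return n_ge / n_splits


def ks_two_sample(x, y, method: str = "auto") -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Parameters
    ----------
    x, y : array-like of float
        The two samples; at least one observation each, all finite.
    method : {"auto", "asymptotic", "exact"}
        "exact" enumerates every label assignment (feasible only for
        small pooled sizes); "auto" uses exact when n1 + n2 <= 16.

    Notes
    -----
    The asymptotic p-value is approximate in the presence of ties; the
    exact mode is tie-aware by construction. D is always computed on the
    pooled distinct values, so ties are handled consistently.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must contain only finite values")
    if method not in ("auto", "asymptotic", "exact"):
        raise ValueError(f"unknown method {method!r}")

    d = _ks_statistic(x, y)
    total = x.size + y.size
    use_exact = method == "exact" or (method == "auto" and total <= _EXACT_KS_MAX_TOTAL)
    if use_exact and method == "exact" and total > 24:
        raise ValueError("exact enumeration infeasible for n1 + n2 > 24")
    if d == 0.0:
        return KSResult(0.0, 1.0, x.size, y.size,
                        "exact-permutation" if use_exact else "asymptotic")
    if use_exact:
        p = _ks_exact_p(x, y, d)
        return KSResult(d, p, x.size, y.size, "exact-permutation")
    p = _ks_asymptotic_p(d, x.size, y.size)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return KSResult(d, p, x.size, y.size, "asymptotic")


def hypergeom_upper_tail_support(K: int, n: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-tail probabilities P(X >= k) for every k in the support of
    Hypergeometric(N, K, n).

    Returns (ks, tail) where ks runs from max(0, n+K-N) to min(K, n).
    Terms are computed in log-space via log-gamma so genome-scale
    universes (N ~ 20,000) do not overflow, then accumulated with a
    reverse log-sum-exp.
    """
    kmin = max(0, n + K - N)
    kmax = min(K, n)
    ks = np.arange(kmin, kmax + 1)
    logpmf = (
        gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
        + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - n + ks + 1)
        + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1)
    )
    # reverse cumulative logsumexp: tail[i] = log sum_{j >= i} exp(logpmf[j])
    rev = logpmf[::-1]
    acc = np.logaddexp.accumulate(rev)[::-1]
    tail = np.exp(acc)
    return ks, np.minimum(tail, 1.0)


def fisher_one_sided(c: ContingencyCounts) -> float:
    """One-sided (enrichment / upper-tail) Fisher exact test.

    p = sum_{j=k}^{min(K,n)} C(K,j) C(N-K,n-j) / C(N,n), the probability
    of an overlap at least as large as observed under random draws of an
    n-gene query from an N-gene universe containing K signature genes.
    """
    ks, tail = hypergeom_upper_tail_support(c.K, c.n, c.N)
    if c.k <= ks[0]:
        return 1.0
    p = float(tail[c.k - ks[0]])
    return min(max(p, np.finfo(float).tiny), 1.0)


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on length < 3 or zero variance."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt(np.sum(dx * dx)))
    sy = float(np.sqrt(np.sum(dy * dy)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined: zero variance")
    r = float(np.sum(dx * dy) / (sx * sy))
    return min(max(r, -1.0), 1.0)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    q_i = min_{j: p_j >= p_i} m * p_j / rank_j, clipped at 1; the output
    preserves the ordering of the input p-values.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
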