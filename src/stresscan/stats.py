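"""Inferential statistics for the gene-set analyses.

Hypergeometric over-representation of one gene set in another (upper tail,
P(X >= k)), two-sample Kolmogorov-Smirnov enrichment of a gene subset in a
ranked score list, and location tests (Mann-Whitney U and Welch t) for gene
properties such as length. The hypergeometric and KS statistics are
evaluated in log space / directly on ECDFs here; Mann-Whitney and Welch t
delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "hypergeom_sf",
    "OverlapResult",
    "overlap_enrichment",
    "KSResult",
    "ks_rank_enrichment",
    "LocationTestResult",
    "location_tests",
]


def _log_comb(n, k):
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def hypergeom_sf(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts category members (K of N in the universe) in a draw of size n.
    Evaluated as a log-space sum of exact log-pmf terms, stable down to
    p < 1e-300. Returns 1.0 for k <= 0.
    """
    for name, v in (("N", N), ("K", K), ("n", n)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if K > N or n > N:
        raise ValueError("need K <= N and n <= N")
    if int(k) != k:
        raise ValueError("k must be an integer")
    if k <= 0:
        return 1.0
    kmax = min(n, K)
    if k > kmax:
        raise ValueError(f"k={k} impossible: exceeds min(n, K)={kmax}")
    j = np.arange(k, kmax + 1)
    logp = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    return float(min(1.0, np.exp(special.logsumexp(logp))))


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of a drawn set (size n) with a category (size K)
    inside a universe of size N; k is the observed overlap."""

    N: int
    K: int
    n: int
    k: int
    expected: float
    fold_enrichment: float
    p_value: float


def overlap_enrichment(
    set_a: Collection[str], set_b: Collection[str], universe: Collection[str]
) -> OverlapResult:
    """Upper-tail hypergeometric test of |A intersect B| against drawing
    |A| genes uniformly from the universe, with |B| category members."""
    uni = set(universe)
    a, b = set(set_a), set(set_b)
    for name, s in (("setA", a), ("setB", b)):
        extra = s - uni
        if extra:
            raise ValueError(f"{name} not a subset of the universe: {sorted(extra)[:5]} ...")
    N, K, n = len(uni), len(b), len(a)
    k = len(a & b)
    expected = n * K / N if N else 0.0
    fold = k / expected if expected > 0 else float("nan")
    return OverlapResult(
        N=N, K=K, n=n, k=k, expected=expected, fold_enrichment=fold,
        p_value=hypergeom_sf(N, K, n, k),
    )


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    n_subset: int
    n_complement: int


def _ks_D(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample KS statistic sup|ECDF_x - ECDF_y|."""
    both = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), both, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), both, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def ks_rank_enrichment(scores: Mapping[str, float], subset: Collection[str]) -> KSResult:
    """Two-sample KS test of the score distribution of `subset` against its
    complement in `scores` (asymptotic p with effective size mn/(m+n)).

    Used to ask whether one gene set (e.g. high transcription stress) sits
    at the top of another ranked list (e.g. DNA damage).
    """
    sub = set(subset)
    extra = sub - set(scores)
    if extra:
        raise ValueError(f"subset genes without scores: {sorted(extra)[:5]} ...")
    x = np.array([v for g, v in scores.items() if g in sub], dtype=float)
    y = np.array([v for g, v in scores.items() if g not in sub], dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both subset and complement must be non-empty")
    D = _ks_D(x, y)
    en = x.size * y.size / (x.size + y.size)
    p = float(min(1.0, sps.kstwo.sf(D, int(round(en)))))
    return KSResult(D=D, p_value=p, n_subset=x.size, n_complement=y.size)


@dataclass(frozen=True)
class LocationTestResult:
    u_statistic: float
    u_p_value: float
    t_statistic: float
    t_p_value: float
    u_method: str


def location_tests(a: Sequence[float], b: Sequence[float]) -> LocationTestResult:
    """Two-sided Mann-Whitney U and Welch t tests of location.

    U is exact (full enumeration) when both samples have n <= 20 and there
    are no ties, otherwise the normal approximation with tie correction.
    Degenerate variance on both sides makes t meaningless; an error directs
    to the U test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs n >= 1 for the U test")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and no_ties) else "asymptotic"
    u = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    if a.size < 2 or b.size < 2:
        t_stat, t_p = float("nan"), float("nan")
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("both samples have zero variance; use the Mann-Whitney U result")
        t = sps.ttest_ind(a, b, equal_var=False)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
    return LocationTestResult(
        u_statistic=float(u.statistic),
        u_p_value=float(u.pvalue),
        t_statistic=t_stat,
        t_p_value=t_p,
        u_method=method,
    )
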