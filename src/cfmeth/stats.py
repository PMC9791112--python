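"""Group-comparison statistics with exact small-sample rank-sum enumeration.

With three cases against six controls the Wilcoxon rank-sum (Mann-Whitney U)
null distribution has only C(9,3) = 84 equally likely rank assignments, so
the exact two-sided p-value is computed by full enumeration whenever the
combined sample is small and tie-free; the smallest attainable p is then
2/84 ~ 0.0238, reached exactly when the groups separate completely.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 12   # full enumeration up to this combined sample size


@dataclass(frozen=True)
class RankSumResult:
    U: float               # number of (x, y) pairs with x > y (ties count 1/2)
    p_two_sided: float
    method: str            # "exact" or "normal-approximation"


@lru_cache(maxsize=64)
def _exact_u_distribution(n1: int, n2: int) -> tuple[np.ndarray, int]:
    """Counts of each U value over all C(n1+n2, n1) rank assignments.

    U for a rank subset S (the ranks of group 1 among 0..n-1) is
    sum(S) - n1(n1-1)/2; returns (counts indexed by U, total assignments).
    """
    n = n1 + n2
    counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
    offset = n1 * (n1 - 1) // 2
    for ranks in combinations(range(n), n1):
        counts[sum(ranks) - offset] += 1
    return counts, comb(n, n1)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def exact_rank_sum(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    For combined samples of at most 12 tie-free values the p-value is exact:
    2 * min(P(U <= u), P(U >= u)) over the full enumeration of rank
    assignments, capped at 1.  Larger or tied samples fall back to the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2

    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        counts, total = _exact_u_distribution(n1, n2)
        ui = int(round(u))
        lower = counts[: ui + 1].sum() / total
        upper = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return RankSumResult(u, p, "exact")

    # normal approximation, tie-corrected variance, continuity correction
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return RankSumResult(u, 1.0, "normal-approximation")
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return RankSumResult(u, float(p), "normal-approximation")


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value.

    Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)
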