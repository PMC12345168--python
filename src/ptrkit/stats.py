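"""Nonparametric paired and two-sample tests.

The exact Wilcoxon signed-rank null is built by dynamic programming over
all 2^n sign assignments of the (tie-averaged) ranks, so small-sample
p-values are exact even in the presence of tied absolute differences.
Zeros are dropped (the classical Wilcoxon convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import UndefinedCorrelationError

# DP over sign assignments is exact as long as 2^n fits an IEEE double
# exactly; 40 comfortably covers the 36-pair all-condition comparison
EXACT_LIMIT = 40

ALTERNATIVES = ("greater", "less", "two-sided")


@dataclass
class SignedRankResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float  # NaN when degenerate
    n: int  # nonzero differences used
    alternative: str
    degenerate: bool = False
    method: str = "exact"


def _exact_signed_rank_distribution(ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per value of 2*W+ (index = 2*W+)."""
    scaled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(scaled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return counts


def signed_rank_test(before, after=None, alternative: str = "greater") -> SignedRankResult:
    """Paired Wilcoxon signed-rank test.

    Parameters
    ----------
    before, after
        Paired measurements; if ``after`` is None, ``before`` is taken to
        be the vector of differences directly.
    alternative
        ``"greater"`` tests whether ``after`` exceeds ``before``
        (differences positive), ``"less"`` the reverse.

    Exact null by enumeration for n <= 40 nonzero differences, normal
    approximation with tie correction and continuity correction above.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    before = np.asarray(before, dtype=float)
    if after is None:
        diffs = before
    else:
        diffs = np.asarray(after, dtype=float) - before
    if diffs.size == 0:
        raise ValueError("no pairs supplied")
    nonzero = diffs[diffs != 0]
    n = nonzero.size
    if n == 0:
        return SignedRankResult(np.nan, np.nan, 0, alternative, degenerate=True)

    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())

    if n <= EXACT_LIMIT:
        counts = _exact_signed_rank_distribution(ranks)
        total = counts.size - 1  # == 2 * n(n+1)/2
        denom = counts.sum()  # 2^n
        k = int(np.rint(2.0 * w_plus))
        p_greater = counts[k:].sum() / denom
        p_less = counts[: k + 1].sum() / denom
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            mirror = total - k
            if k == mirror:
                p = 1.0
            elif k > mirror:
                p = p_greater + counts[: mirror + 1].sum() / denom
            else:
                p = p_less + counts[mirror:].sum() / denom
            p = min(1.0, p)
        return SignedRankResult(w_plus, float(p), n, alternative, method="exact")

    # normal approximation with tie + continuity correction
    mean = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise UndefinedCorrelationError("zero variance in signed-rank null")
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (abs(w_plus - mean) - 0.5) / sd
        p = 2.0 * sps.norm.sf(z)
        p = min(1.0, p)
    return SignedRankResult(w_plus, float(p), n, alternative, method="normal")


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    n_x: int
    n_y: int
    alternative: str
    method: str


def rank_sum_test(x, y, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when the smaller sample has <= 10 observations and there are no
    ties; otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), x.size, y.size,
                         alternative, method)
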