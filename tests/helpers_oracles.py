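"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own engine code: interval logic is
checked per base against boolean membership arrays, the OLS slope test is
recomputed from closed-form sums, and Poisson tails are summed term by
term.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def perbase_membership(intervals, genome_size: int) -> np.ndarray:
    """Boolean occupancy array over a single-chromosome toy genome."""
    mask = np.zeros(genome_size, dtype=bool)
    for iv in intervals:
        mask[iv.start:iv.end] = True
    return mask


def perbase_intersection_bp(a, b, genome_size: int) -> int:
    return int((perbase_membership(a, genome_size)
                & perbase_membership(b, genome_size)).sum())


def perbase_coverage_fraction(target, by, genome_size: int) -> float:
    mask = perbase_membership(by, genome_size)
    return float(mask[target.start:target.end].mean())


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) half-open pairs."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def ols_slope_pvalue(x: np.ndarray, y: np.ndarray):
    """Closed-form simple OLS slope, SE and two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = (resid ** 2).sum() / (n - 2)
    se = math.sqrt(s2 / sxx)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return slope, p


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), by direct term summation."""
    if k <= 0:
        return 1.0
    # sum the lower tail and subtract, accumulating terms recursively
    term = math.exp(-lam)
    cdf = term
    for i in range(1, k):
        term *= lam / i
        cdf += term
    return max(0.0, 1.0 - cdf)


def pwm_raw_score(seq: str, matrix: np.ndarray) -> float:
    """Brute-force log2 sum of column probabilities for one window."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return sum(math.log2(matrix[idx[b], j]) for j, b in enumerate(seq))


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0
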