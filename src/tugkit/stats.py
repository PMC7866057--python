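"""Paired comparison of stride-length series: Wilcoxon signed rank and RMSE.

The insole-derived and radar-derived stride lengths over the same strides
form paired samples.  The Wilcoxon signed-rank test (two-sided, zero
differences discarded, tied absolute differences mid-ranked) tests the null
hypothesis that the median paired difference is zero.  For n <= 15 retained
pairs the null distribution is obtained exactly by enumerating all 2^n sign
assignments of the realized ranks; above that, a normal approximation with
continuity and tie corrections is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["PairedComparison", "wilcoxon_signed_rank", "rmse", "compare_paired"]

EXACT_LIMIT = 15


@dataclass(frozen=True)
class PairedComparison:
    statistic: float      # min of the positive/negative rank sums
    p_value: float        # two-sided
    n_pairs: int          # pairs retained after dropping zero differences
    rmse: float
    method: str           # "exact" or "approx"

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns ``(W, p)`` where W is the smaller of the positive- and
    negative-rank sums.  ``method`` is "exact" (sign enumeration),
    "approx" (normal with continuity and tie corrections) or "auto"
    (exact for n <= 15).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)

    if method == "auto":
        method = "exact" if n <= EXACT_LIMIT else "approx"
    if method == "exact":
        # enumerate all sign assignments of the realized (possibly tied) ranks
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        total_sum = ranks.sum()
        w_opp = total_sum - w
        lo, hi = min(w, w_opp), max(w, w_opp)
        p = (np.sum(totals <= lo + 1e-12) + np.sum(totals >= hi - 1e-12)) / totals.size
        return w, float(min(1.0, p))
    if method != "approx":
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    mean = n * (n + 1) / 4.0
    # tie correction on the variance of the rank sum
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean + 0.5) / np.sqrt(var)  # continuity corrected
    p = 2.0 * norm.cdf(z)
    return w, float(min(1.0, p))


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square difference between two equal-length series."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("series must have equal nonzero length")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def compare_paired(
    insole: np.ndarray, radar: np.ndarray, method: str = "auto"
) -> PairedComparison:
    """Full paired comparison of insole vs radar stride lengths."""
    w, p = wilcoxon_signed_rank(insole, radar, method=method)
    d = np.asarray(insole, float) - np.asarray(radar, float)
    n = int(np.sum(d != 0))
    used = "exact" if (method == "exact" or (method == "auto" and n <= EXACT_LIMIT)) else "approx"
    return PairedComparison(
        statistic=w,
        p_value=p,
        n_pairs=n,
        rmse=rmse(insole, radar),
        method=used,
    )
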