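"""Paired and two-sample tests plus the summary conventions of the assay.

Secretion comparisons are paired per cell across membranes, so the
primary test is the Wilcoxon signed-rank test: zero differences are
discarded (Wilcoxon's original treatment), tied absolute differences get
midranks, and the two-sided p-value comes from the exact null
distribution of W+ (all 2^n sign assignments, computed by dynamic
programming over doubled midranks, which is exactly equivalent to
enumeration) for n <= 25, or from the normal approximation with tie and
continuity corrections for larger n.  Viability comparisons between
treatment groups use Welch's two-sample t-test (unequal variances,
Satterthwaite degrees of freedom).

Significance stars follow the assay's convention: * p < 0.05,
** p < 0.001, *** p < 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "DegenerateDataError", "wilcoxon_signed_rank",
           "welch_t", "summary_stats", "significance_stars"]

EXACT_N_MAX = 25


class DegenerateDataError(ValueError):
    """The data admit no test (e.g. all paired differences are zero)."""


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    stars: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stars", significance_stars(self.p_value))


def _signed_rank_exact_pvalue(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for W+ given the |difference| midranks.

    Doubled midranks are integers, so the null distribution of 2*W+ over
    all sign assignments is built by polynomial convolution -- identical
    to brute-force enumeration of the 2^n sign vectors.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a, b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples a, b.

    Reports W+, the rank sum of the pairs with b > a.  Requires at least
    5 non-zero differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 5:
        raise DegenerateDataError(
            f"only {n} non-zero differences; at least 5 are required")
    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        p = _signed_rank_exact_pvalue(w_plus, ranks)
        method = "wilcoxon_signed_rank_exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            raise DegenerateDataError("zero variance in signed ranks")
        diff = w_plus - mean
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)  # continuity corr.
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "wilcoxon_signed_rank_normal"
    return TestResult(statistic=w_plus, p_value=p, n=n, method=method)


def welch_t(x, y) -> TestResult:
    """Welch's two-sample t-test (two-sided, unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            raise DegenerateDataError(
                "both samples have zero variance and equal means")
        return TestResult(statistic=float("inf") * np.sign(x.mean() - y.mean()),
                          p_value=0.0, n=x.size + y.size, method="welch_t")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=int(x.size + y.size), method="welch_t")


def summary_stats(values) -> dict[str, float]:
    """Mean, sample SD, and box-plot quartiles (median = Q2).

    Quartiles use linear interpolation between order statistics.  A
    single observation reports SD 0 with ``sd_defined`` False.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 1:
        raise ValueError("summary_stats requires at least one value")
    out = {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "sd_defined": v.size > 1,
        "median": float(np.quantile(v, 0.5)),
        "q1": float(np.quantile(v, 0.25)),
        "q3": float(np.quantile(v, 0.75)),
    }
    return out
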