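"""Agreement and paired-comparison statistics.

The intra-subject design compares per-subject phase means with a
normality-gated paired test: Shapiro–Wilk on the paired differences routes to
the paired t-test (normal) or the Wilcoxon signed-rank test (otherwise).
Method agreement is summarised by Bland–Altman bias and limits of agreement
(bias ± 1.96·SD of the differences) and by Lin's concordance correlation
coefficient with the McBride strength categories.

No multiple-testing correction is applied across the eleven SQI comparisons;
results carry the count of tests so readers can judge the family-wise level.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .exceptions import DataError, ParameterError


@dataclass
class PairedTestResult:
    """Outcome of one normality-gated paired comparison."""

    test: str  # "paired_t" or "wilcoxon"
    statistic: float  # t value, or Wilcoxon V (sum of positive ranks)
    p: float
    df: int | None = None
    z: float | None = None  # normal-approximation z for the Wilcoxon path
    normality_W: float | None = None
    normality_p: float | None = None
    mean_diff: float = float("nan")
    sd_diff: float = float("nan")
    n: int = 0
    note: str = ""


#: McBride strength categories for Lin's CCC
STRENGTHS = ("almost_perfect", "substantial", "moderate", "poor")


@dataclass
class AgreementResult:
    """Bland–Altman bias/limits of agreement plus Lin's CCC for one vital sign."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ccc: float = float("nan")
    strength: str = ""
    n: int = 0


def shapiro_wilk(diffs) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p-value (Royston's AS R94, via scipy)."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if not (3 <= len(d) <= 5000):
        raise DataError("Shapiro–Wilk requires 3 ≤ n ≤ 5000 finite values")
    if np.ptp(d) == 0:
        raise DataError("Shapiro–Wilk undefined for constant input")
    res = spstats.shapiro(d)
    return float(res.statistic), float(res.pvalue)


def paired_t(a, b) -> PairedTestResult:
    """Two-sided paired t-test on per-subject means; df = n − 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise DataError("paired t-test needs two equal-length series, n ≥ 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise DataError("zero-variance differences: paired t undefined")
    res = spstats.ttest_rel(a, b)
    return PairedTestResult(
        test="paired_t",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=len(a) - 1,
        mean_diff=float(np.mean(d)),
        sd_diff=float(np.std(d, ddof=1)),
        n=len(a),
    )


def _wilcoxon_exact_sf(n: int) -> np.ndarray:
    """Counts of sign patterns per rank-sum V for ranks 1..n (DP over 2ⁿ)."""
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts


def wilcoxon_signed_rank(a, b=None) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test; V = sum of positive ranks.

    Zero differences are dropped; |d| is ranked with midranks for ties.  The
    p-value is exact (full enumeration over sign patterns) when the number of
    nonzero differences is ≤ 25 and there are no ties, else a normal
    approximation with tie and continuity corrections.  The z statistic of
    the approximation is always reported alongside V.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise DataError("all differences are zero: Wilcoxon undefined")
    ranks = spstats.rankdata(np.abs(d))
    v = float(np.sum(ranks[d > 0]))
    mean_v = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var_v = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_v > 0:
        cc = 0.5 * np.sign(v - mean_v)
        z = (v - mean_v - cc) / np.sqrt(var_v)
    else:
        z = 0.0
    has_ties = bool(np.any(tie_counts > 1))
    if n <= 25 and not has_ties:
        counts = _wilcoxon_exact_sf(n)
        total = counts.sum()
        vi = int(round(v))
        p_le = counts[: vi + 1].sum() / total
        p_ge = counts[vi:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        p = 2.0 * spstats.norm.sf(abs(z))
    return PairedTestResult(
        test="wilcoxon",
        statistic=v,
        p=float(p),
        z=float(z),
        mean_diff=float(np.mean(d)),
        sd_diff=float(np.std(d, ddof=1)) if n > 1 else float("nan"),
        n=n,
    )


def test_sqi_phase_difference(
    no_flight, in_flight, alpha: float = 0.05
) -> PairedTestResult:
    """Normality-gated intra-subject phase comparison of per-subject means.

    Differences are in-flight − no-flight.  Shapiro–Wilk on the differences
    routes to the paired t-test when normality is not rejected at ``alpha``,
    else to the Wilcoxon signed-rank test.  All-zero differences are reported
    as "no difference" with p = 1.
    """
    a = np.asarray(in_flight, dtype=float)
    b = np.asarray(no_flight, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise DataError("need at least 3 subjects with both phases")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(
            test="wilcoxon",
            statistic=float("nan"),
            p=1.0,
            mean_diff=0.0,
            sd_diff=0.0,
            n=len(d),
            note="no difference (all paired differences zero)",
        )
    w, w_p = shapiro_wilk(d)
    if w_p >= alpha:
        result = paired_t(a, b)
    else:
        result = wilcoxon_signed_rank(a, b)
    result.normality_W = w
    result.normality_p = w_p
    return result


def bland_altman(ear, ref) -> AgreementResult:
    """Bland–Altman bias and limits of agreement (bias ± 1.96·sample SD).

    Pairs with a missing value on either side are dropped.
    """
    x = np.asarray(ear, dtype=float)
    y = np.asarray(ref, dtype=float)
    if len(x) != len(y):
        raise DataError("paired series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    if len(d) < 2:
        raise DataError("need at least 2 complete pairs")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=len(d),
    )


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError("paired series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 2:
        raise DataError("need at least 2 complete pairs")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    if sx2 == 0 and sy2 == 0:
        raise DataError("CCC undefined for two constant series")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return 2.0 * sxy / (sx2 + sy2 + (float(x.mean()) - float(y.mean())) ** 2)


def mcbride_strength(ccc: float) -> str:
    """McBride category: >0.99 almost perfect; >0.95 substantial; >0.90 moderate; else poor."""
    if not (-1.0 - 1e-12 <= ccc <= 1.0 + 1e-12):
        raise ParameterError("CCC must lie in [−1, 1]")
    if ccc > 0.99:
        return "almost_perfect"
    if ccc > 0.95:
        return "substantial"
    if ccc > 0.90:
        return "moderate"
    return "poor"


def agreement(ear, ref) -> AgreementResult:
    """Bland–Altman plus CCC plus strength category in one result."""
    result = bland_altman(ear, ref)
    result.ccc = lin_ccc(ear, ref)
    result.strength = mcbride_strength(result.ccc)
    return result
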