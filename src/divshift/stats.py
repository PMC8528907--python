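"""Group summaries and hypothesis tests for disturbed-vs-control contrasts.

The reporting convention mirrors small-n ecological summary tables: per
group a mean, sample SD (n-1 denominator), n, and an Anderson-Darling
normality p-value that is *not computed* for n < 8 (the test has essentially
no power there); groups are then compared with a two-tailed Welch's t-test
at alpha 0.05.  The Welch test operates on (mean, sd, n) summaries so that
published summary rows can be re-tested directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "WelchResult",
    "ADResult",
    "summarize_group",
    "welch_t_test",
    "anderson_darling_normality",
    "compare_groups",
    "AD_MIN_N",
    "DEFAULT_ALPHA",
]

AD_MIN_N = 8
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ADResult:
    """Anderson-Darling normality test (mean and variance estimated)."""

    A2: float
    A2_star: float  # small-sample adjusted: A2 * (1 + 0.75/n + 2.25/n^2)
    p: float


@dataclass(frozen=True)
class GroupSummary:
    group: str
    mean: float
    sd: float
    n: int
    ad_p: float | None = None  # None <=> "not computed" (n < 8)
    ad_status: Literal["ok", "not computed", "degenerate"] = "not computed"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group summary requires n >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    significant: bool
    alpha: float = DEFAULT_ALPHA


def summarize_group(values: Sequence[float], group: str = "") -> GroupSummary:
    """Mean, sample SD and AD normality screen for one group's values."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if x.size < AD_MIN_N:
        ad_p, status = None, "not computed"
    elif sd == 0.0:
        ad_p, status = None, "degenerate"
    else:
        ad_p, status = anderson_darling_normality(x).p, "ok"
    return GroupSummary(group, mean, sd, int(x.size), ad_p, status)


def welch_t_test(
    summary1: GroupSummary, summary2: GroupSummary, alpha: float = DEFAULT_ALPHA
) -> WelchResult:
    """Two-tailed Welch's t-test from two group summaries.

        t  = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)
        df = (s1^2/n1 + s2^2/n2)^2 /
             [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ]   (Welch-Satterthwaite)

    The sign of t follows mean1 - mean2; p is symmetric under group swap.
    """
    if summary1.n < 2 or summary2.n < 2:
        raise ValueError("Welch's t-test requires n >= 2 in both groups")
    v1 = summary1.sd**2 / summary1.n
    v2 = summary2.sd**2 / summary2.n
    diff = summary1.mean - summary2.mean
    if v1 + v2 == 0.0:
        if diff == 0.0:
            raise ValueError(
                "both groups have zero variance and equal means; t is undefined"
            )
        t = math.inf if diff > 0 else -math.inf
        df = float(summary1.n + summary2.n - 2)
        p = 0.0
    else:
        t = diff / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (
            v1**2 / (summary1.n - 1) + v2**2 / (summary2.n - 1)
        )
        p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p, p < alpha, alpha)


def _ad_statistic(x: np.ndarray) -> tuple[float, float]:
    """A2 and adjusted A2* for normality with estimated mean and variance."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    log_cdf = sps.norm.logcdf(z)
    log_sf = sps.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (log_cdf + log_sf[::-1])) / n
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    return float(a2), float(a2_star)


def _ad_pvalue(a2_star: float) -> float:
    """D'Agostino-Stephens piecewise approximation for the normality case."""
    a = a2_star
    if a >= 0.6:
        p = math.exp(1.2937 - 5.709 * a + 0.0186 * a * a)
    elif a >= 0.34:
        p = math.exp(0.9177 - 4.279 * a - 1.38 * a * a)
    elif a > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a - 59.938 * a * a)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a - 223.73 * a * a)
    return min(max(p, 0.0), 1.0)


def anderson_darling_normality(values: Sequence[float]) -> ADResult | None:
    """Anderson-Darling normality test; returns None ("not computed") for n < 8."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < AD_MIN_N:
        return None
    if x.std(ddof=1) == 0.0:
        raise ValueError("Anderson-Darling statistic undefined for zero variance")
    a2, a2_star = _ad_statistic(x)
    return ADResult(a2, a2_star, _ad_pvalue(a2_star))


def compare_groups(
    disturbed: Sequence[float],
    control: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[GroupSummary, GroupSummary, WelchResult]:
    """Bundle per-group summaries and the Welch test into one table row."""
    if len(disturbed) < 2 or len(control) < 2:
        raise ValueError("group comparison requires n >= 2 per group")
    s_dist = summarize_group(disturbed, "disturbed")
    s_ctrl = summarize_group(control, "control")
    return s_dist, s_ctrl, welch_t_test(s_dist, s_ctrl, alpha=alpha)
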