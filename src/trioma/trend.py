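"""Trend statistics: Pearson correlation over a timecourse, a one-sample t
against the baseline, and a summary-statistic two-sample t, each with a
significance grade.

Grades follow the two-level convention used for timecourse expression
summaries: a single mark for p < 0.10, a double mark for p < 0.05.  The
maturation/injury trend columns use "*"/"**"; the 2 hr vs 4 hr comparison
uses "#"/"##".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrendResult",
    "TTestResult",
    "pearson_trend",
    "one_sample_t",
    "two_sample_t_summary",
    "grade_p",
]


@dataclass(frozen=True)
class TrendResult:
    """Pearson R of SLR against time; ``r is None`` marks an undefined R
    (zero variance in the series)."""

    r: float | None
    n: int

    @property
    def defined(self) -> bool:
        return self.r is not None


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    grade: str  # "", "*", "**" or "", "#", "##"
    tail: str  # "one" | "two"


def grade_p(p: float, symbol: str = "*", alpha_weak: float = 0.10,
            alpha_strong: float = 0.05) -> str:
    """Two-level significance mark: double below alpha_strong, single below
    alpha_weak, empty otherwise."""
    if p < alpha_strong:
        return symbol * 2
    if p < alpha_weak:
        return symbol
    return ""


def pearson_trend(series, times) -> TrendResult:
    """Sample Pearson correlation of SLR values against their timepoints.

    The series includes the baseline (SLR = 0 at the baseline time).  A
    zero-variance series has no defined correlation and returns ``r=None``
    rather than 0.
    """
    y = np.asarray(series, dtype=float)
    x = np.asarray(times, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("need >=3 (time, SLR) points of equal length")
    if not (np.diff(x) > 0).all():
        raise ValueError("times must be strictly increasing")
    yc = y - y.mean()
    xc = x - x.mean()
    denom = math.sqrt((xc * xc).sum() * (yc * yc).sum())
    if (yc == 0).all() or denom == 0:
        return TrendResult(r=None, n=y.size)
    return TrendResult(r=float((xc * yc).sum() / denom), n=y.size)


def one_sample_t(observations, mu: float = 0.0, tail: str = "one",
                 symbol: str = "*") -> TTestResult:
    """One-sample t of the observations against ``mu``.

    With ``tail="one"`` the p-value is taken in the direction of the
    observed mean deviation (p = P(T >= |t|)), the convention under which
    two post-baseline SLR values graded at alpha 0.10/0.05 reproduce the
    published timecourse marks.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size < 2:
        raise ValueError("need >=2 observations")
    n = obs.size
    df = n - 1
    sd = obs.std(ddof=1)
    mean = obs.mean()
    if sd == 0:
        if mean == mu:
            return TTestResult(t=0.0, df=df, p=1.0, grade="", tail=tail)
        t = math.copysign(math.inf, mean - mu)
        p = float(np.nextafter(0, 1))
        return TTestResult(t=t, df=df, p=p, grade=symbol * 2, tail=tail)
    t = (mean - mu) / (sd / math.sqrt(n))
    if tail == "one":
        p = float(stats.t.sf(abs(t), df))
    elif tail == "two":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ValueError("tail must be 'one' or 'two'")
    return TTestResult(t=float(t), df=df, p=p, grade=grade_p(p, symbol), tail=tail)


def two_sample_t_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int,
                         symbol: str = "#") -> TTestResult:
    """Pooled-variance two-sample t from summary statistics, two-tailed."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if pooled == 0:
        if mean1 == mean2:
            return TTestResult(t=0.0, df=df, p=1.0, grade="", tail="two")
        t = math.copysign(math.inf, mean2 - mean1)
        p = float(np.nextafter(0, 1))
        return TTestResult(t=t, df=df, p=p, grade=symbol * 2, tail="two")
    se = math.sqrt(pooled * (1 / n1 + 1 / n2))
    t = (mean2 - mean1) / se
    p = float(2 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p, grade=grade_p(p, symbol), tail="two")
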