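"""The study's inferential statistics, implemented from first principles.

Welch's unpaired t-test (Welch-Satterthwaite fractional df), the paired
Student's t-test, and Pearson's correlation with its t-transform
p-value.  All p-values are two-sided, evaluated through the regularized
incomplete beta function: for Student's t with ``df`` degrees of
freedom,

    P(|T| > |t|) = I_{df/(df + t^2)}(df/2, 1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

from .core import DegenerateSignalError, ParameterError, UndefinedCorrelationError

__all__ = ["TestResult", "welch_t", "paired_t", "pearson", "t_sf_two_sided"]


@dataclass(frozen=True)
class TestResult:
    """Result of a significance test.

    ``statistic`` is t (or r for Pearson), ``df`` the degrees of freedom
    (fractional for Welch), ``p`` the two-sided p-value, ``estimate`` a
    mean difference (t-tests) or r² (Pearson).  ``degenerate`` flags
    zero-variance forced cases where the statistic is infinite.
    """

    statistic: float
    df: float
    p: float
    estimate: float
    kind: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ParameterError(f"p-value {self.p} outside [0, 1]")

    def format(self) -> str:
        """The journal-style line ``t = ..., df = ..., P = ...``."""
        stat_name = "r" if self.kind == "pearson" else "t"
        p = "<0.0001" if self.p < 1e-4 else f"{self.p:.4g}"
        return f"{stat_name} = {self.statistic:.4g}, df = {self.df:.4g}, P = {p}"


def t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided tail probability of Student's t via the incomplete beta."""
    if df <= 0:
        raise ParameterError("df must be positive")
    if math.isinf(t):
        return 0.0
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


def welch_t(x, y) -> TestResult:
    """Two-sided Welch's t-test (unequal variances, unequal n)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ParameterError("each sample needs n >= 2")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx == 0 and vy == 0:
        raise DegenerateSignalError("both samples have zero variance")
    diff = float(np.mean(x) - np.mean(y))
    se2 = vx / nx + vy / ny
    t = diff / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return TestResult(
        statistic=t, df=df, p=t_sf_two_sided(t, df), estimate=diff, kind="welch"
    )


def paired_t(x, y) -> TestResult:
    """Two-sided paired Student's t-test on ``x - y``.

    A constant nonzero shift (zero-variance differences) is reported as
    an infinite statistic with ``p = 0`` and ``degenerate=True`` rather
    than an error; identical samples (all-zero differences) raise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ParameterError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ParameterError("need n >= 2 pairs")
    d = x - y
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    df = float(n - 1)
    if sd_d == 0:
        if mean_d == 0:
            raise DegenerateSignalError("all paired differences are zero")
        t = math.inf if mean_d > 0 else -math.inf
        return TestResult(
            statistic=t, df=df, p=0.0, estimate=mean_d, kind="paired",
            degenerate=True,
        )
    t = mean_d / (sd_d / math.sqrt(n))
    return TestResult(
        statistic=t, df=df, p=t_sf_two_sided(t, df), estimate=mean_d, kind="paired"
    )


def pearson(x, y) -> TestResult:
    """Pearson product-moment correlation with two-sided p (df = n - 2)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ParameterError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ParameterError("need n >= 3 for a correlation")
    dx = x - np.mean(x)
    dy = y - np.mean(y)
    ssx = float(np.dot(dx, dx))
    ssy = float(np.dot(dy, dy))
    if ssx == 0 or ssy == 0:
        raise UndefinedCorrelationError("constant input; correlation undefined")
    r = float(np.dot(dx, dy) / math.sqrt(ssx * ssy))
    r = max(-1.0, min(1.0, r))
    df = float(n - 2)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = t_sf_two_sided(t, df)
    return TestResult(statistic=r, df=df, p=p, estimate=r * r, kind="pearson")
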