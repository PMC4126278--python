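"""Reliability and construct-validity statistics for CDI validation.

Implements the validation toolkit for an imaging biomarker: single-rater
intraclass correlations from the two-way ANOVA decomposition (Shrout &
Fleiss models 2 and 1 / 3), the standardized response mean, Spearman
correlation, linear trend across ordinal severity grades treated as
continuous, independent two-sample t-tests, stratified group summaries,
and percent-difference reporting.

ICC conventions (k raters, n targets; MSR / MSC / MSE the row, column and
residual mean squares of the two-way layout):

    ICC(3,1) = (MSR - MSE) / (MSR + (k - 1) MSE)              raters fixed
    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC-MSE)) raters random

Model 3 suits intra-tester designs (sessions of one rater); model 2 suits
inter-tester designs where raters are a random sample and systematic
rater shifts should count against agreement.

Undefined statistics (zero variance, constant inputs) raise
:class:`~kneecdi.errors.UndefinedStatisticError` rather than returning a
sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedStatisticError, ValidationError


@dataclass
class RatingsMatrix:
    """Complete n-targets x k-raters measurement layout.

    For intra-tester reliability the "raters" axis holds the k sessions of
    a single rater.  Missing cells are not supported (listwise complete).
    """

    values: np.ndarray
    targets: list[str] | None = None
    raters: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("ratings must be a 2-D targets x raters array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValidationError("need >= 2 targets and >= 2 raters")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ratings contain missing or non-finite cells")
        if self.targets is None:
            self.targets = [f"t{i}" for i in range(n)]
        if self.raters is None:
            self.raters = [f"r{j}" for j in range(k)]
        if len(self.targets) != n or len(self.raters) != k:
            raise ValidationError("label lengths do not match the matrix")


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way single-measurement ANOVA layout."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    return (
        ss_rows / (n - 1),
        ss_cols / (k - 1),
        ss_err / ((n - 1) * (k - 1)),
    )


def icc(matrix: RatingsMatrix, model: Literal["2,1", "3,1"]) -> float:
    """Single-rater intraclass correlation, Shrout–Fleiss model 2 or 3."""
    x = matrix.values
    n, k = x.shape
    msr, msc, mse = _two_way_mean_squares(x)
    denom3 = msr + (k - 1) * mse
    if denom3 <= 0 or np.allclose(x, x.flat[0]):
        raise UndefinedStatisticError(
            "ICC undefined: ratings carry no variance"
        )
    if model == "3,1":
        return float((msr - mse) / denom3)
    if model == "2,1":
        denom2 = denom3 + (k / n) * (msc - mse)
        if denom2 == 0:
            raise UndefinedStatisticError("ICC(2,1) undefined: zero denominator")
        return float((msr - mse) / denom2)
    raise ValidationError(f"unknown ICC model {model!r}")


def srm(changes: Sequence[float]) -> float:
    """Standardized response mean: mean change / SD of change (SD with n-1)."""
    c = np.asarray(changes, dtype=float)
    if c.ndim != 1 or len(c) < 2:
        raise ValidationError("SRM needs >= 2 change scores")
    sd = c.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("SRM undefined: zero change variance")
    return float(c.mean() / sd)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need two equal-length vectors of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("Spearman undefined for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class TrendResult:
    """OLS linear-trend fit of an outcome on an ordinal grade."""

    slope: float
    stderr: float
    t: float
    p: float
    n: int
    intercept: float


def linear_trend(values: Sequence[float], grade: Sequence[float]) -> TrendResult:
    """Test for a linear trend across severity grades treated as continuous.

    Ordinary least squares of the outcome on the grade; the p-value is the
    two-sided t-test of the slope on n - 2 degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(grade, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValidationError("values and grades must be equal-length vectors")
    if len(y) < 3:
        raise ValidationError("linear trend needs >= 3 observations")
    if np.ptp(g) == 0:
        raise ValidationError("linear trend needs >= 2 distinct grades")
    fit = sps.linregress(g, y)
    if fit.stderr > 0:
        tstat = fit.slope / fit.stderr
    else:
        tstat = np.inf * np.sign(fit.slope) if fit.slope != 0 else 0.0
    return TrendResult(
        slope=float(fit.slope),
        stderr=float(fit.stderr),
        t=float(tstat),
        p=float(fit.pvalue),
        n=len(y),
        intercept=float(fit.intercept),
    )


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: Literal["welch", "pooled"] = "welch",
) -> tuple[float, float]:
    """Independent two-sample t-test; Welch (unequal variances) by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 observations")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def group_summary(
    records: pd.DataFrame,
    stratifier: str,
    outcome: str,
) -> pd.DataFrame:
    """Stratified descriptives plus the linear-trend p across strata.

    One row per stratum with n, mean, sd; the returned frame carries the
    trend fit over all non-empty strata in ``attrs['trend']`` (None when a
    single stratum makes the trend undefined, which is also flagged in
    ``attrs['trend_error']``).
    """
    if stratifier not in records or outcome not in records:
        raise ValidationError(
            f"records need columns {stratifier!r} and {outcome!r}"
        )
    df = records[[stratifier, outcome]].dropna()
    rows = []
    for g, sub in df.groupby(stratifier, sort=True):
        vals = sub[outcome].to_numpy(dtype=float)
        rows.append(
            {
                stratifier: g,
                "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    try:
        trend = linear_trend(df[outcome].to_numpy(), df[stratifier].to_numpy())
        out.attrs["trend"] = trend
        out.attrs["trend_error"] = None
    except ValidationError as exc:
        out.attrs["trend"] = None
        out.attrs["trend_error"] = str(exc)
    return out


def percent_reduction(reference_mean: float, comparison_mean: float) -> int:
    """Percent reduction of a comparison group relative to a reference.

    ``100 * (1 - comparison / reference)``, rounded to the nearest integer
    for reporting (e.g. how much lower the CDI of severe knees is than
    that of undamaged knees).
    """
    if not reference_mean > 0:
        raise ValidationError("reference mean must be positive")
    return int(round(100.0 * (1.0 - comparison_mean / reference_mean)))


def sample_with_moments(mean: float, sd: float, n: int, seed: int = 0) -> np.ndarray:
    """A sample of size n with *exactly* the requested mean and sd (n-1).

    Useful for worked examples quoted as summary moments: draw a shape,
    standardize it, and rescale, so any moment-only statistic (such as the
    SRM) is reproduced exactly.
    """
    if n < 2:
        raise ValidationError("need n >= 2")
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    z = z - z.mean()
    s = z.std(ddof=1)
    if s == 0:  # pathological draw; fall back to a deterministic shape
        z = np.linspace(-1, 1, n)
        z = z - z.mean()
        s = z.std(ddof=1)
    return mean + sd * z / s
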