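"""Statistical comparison of calibration curves across conditions.

Two GPI-vs-chlorophyll datasets (a control and an environmental condition
such as reduced sample volume, high pH or bacterial contamination) are
compared with an ANCOVA-style general linear model: the full model fits a
separate slope and intercept per group, and the group-by-concentration
interaction is F-tested against it.  Only if the slopes are compatible is
the interaction dropped and the group term (intercept difference) tested
in the common-slope model.  Residual normality is summarised (skewness and
excess kurtosis of the full-model residuals) but not enforced.

The module also quantifies the practical consequence of using the control
standard curve under interference (signed percentage error at the maximum
and half-maximum measurable concentrations) and performs the sensitivity
power analysis: the smallest slope difference detectable at a given alpha
and power for the realised design (sample sizes, x spreads, residual
scatter), via the noncentral-t power function of the two-sample slope
test.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .calibration import CalibrationCurve, CalibrationPoint
from .errors import InvalidCurveError, NumericalError, ValidationError

__all__ = [
    "CurveComparison",
    "InterferenceErrorTable",
    "PowerSpec",
    "compare_curves",
    "interference_error_table",
    "detectable_slope_difference",
    "slope_difference_power",
    "ssx_of",
]


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept a sequence of CalibrationPoint or an (x, y) array pair."""
    if len(data) == 2 and not isinstance(data[0], CalibrationPoint):
        x, y = np.asarray(data[0], float), np.asarray(data[1], float)
        if x.shape != y.shape:
            raise ValidationError("x and y must have the same length")
        return x, y
    x = np.asarray([p.chl for p in data], float)
    y = np.asarray([p.gpi_final for p in data], float)
    return x, y


def _sums(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ xc), float(xc @ yc), float(yc @ yc)


@dataclass
class CurveComparison:
    """Slope and (conditionally) intercept F-tests between two datasets."""

    pigment: str
    f_slope: float
    df_slope: tuple[int, int]
    p_slope: float
    slopes_equal: bool
    f_intercept: float | None
    df_intercept: tuple[int, int] | None
    p_intercept: float | None
    intercepts_equal: bool | None
    alpha: float
    n_control: int
    n_variable: int
    residual_skew: float
    residual_kurtosis: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["df_slope"] = list(self.df_slope)
        if self.df_intercept is not None:
            d["df_intercept"] = list(self.df_intercept)
        return d


def _f_ratio(extra_sse: float, mse: float) -> float:
    """F statistic with degenerate (perfect-fit) cases resolved.

    Rounding can make the extra SSE of the reduced model marginally
    negative; it is clamped at zero.  A zero residual mean square with no
    extra SSE (identical perfect-fit groups) gives F = 0.
    """
    extra = max(0.0, extra_sse)
    if mse == 0.0:
        return 0.0 if extra == 0.0 else float("inf")
    return extra / mse


def _ancova_sse(x1, y1, x2, y2) -> tuple[float, float, float, int]:
    """SSEs of the three nested models and the total n.

    Full model (separate lines), common-slope model (group + x) and single
    line, all by closed-form least squares on within-group centered sums.
    """
    sxx1, sxy1, syy1 = _sums(x1, y1)
    sxx2, sxy2, syy2 = _sums(x2, y2)
    if sxx1 == 0 or sxx2 == 0:
        raise NumericalError("a group has no spread in concentration; slopes undefined")
    sse_full = (syy1 - sxy1**2 / sxx1) + (syy2 - sxy2**2 / sxx2)
    sse_common = (syy1 + syy2) - (sxy1 + sxy2) ** 2 / (sxx1 + sxx2)
    xall, yall = np.concatenate([x1, x2]), np.concatenate([y1, y2])
    sxxp, sxyp, syyp = _sums(xall, yall)
    sse_single = syyp - sxyp**2 / sxxp
    # centered-sum subtractions leave float dust where a model fits exactly
    tol = 1e-12 * max(syyp, np.finfo(float).tiny)
    sses = [0.0 if s < tol else float(s) for s in (sse_full, sse_common, sse_single)]
    return sses[0], sses[1], sses[2], xall.size


def compare_curves(
    control,
    variable,
    alpha: float = 0.05,
    pigment: str = "total",
    upper_limit_gpi: float | None = None,
) -> CurveComparison:
    """ANCOVA comparison of two calibration datasets.

    When ``upper_limit_gpi`` (from the control curve's linear interval) is
    given, points above it are excluded from both groups before fitting, so
    the comparison covers only the range where the response is linear.
    The interaction F-test has (1, n - 4) degrees of freedom; the intercept
    test, run only when the slope test is not significant at ``alpha``, has
    (1, n - 3).
    """
    x1, y1 = _as_xy(control)
    x2, y2 = _as_xy(variable)
    if upper_limit_gpi is not None:
        keep1, keep2 = y1 <= upper_limit_gpi, y2 <= upper_limit_gpi
        x1, y1, x2, y2 = x1[keep1], y1[keep1], x2[keep2], y2[keep2]
    if x1.size < 3 or x2.size < 3:
        raise ValidationError(
            f"each group needs >= 3 points in range (got {x1.size} and {x2.size})"
        )
    sse_full, sse_common, sse_single, n = _ancova_sse(x1, y1, x2, y2)

    df_full = n - 4
    f_slope = _f_ratio(sse_common - sse_full, sse_full / df_full)
    p_slope = float(stats.f.sf(f_slope, 1, df_full))

    # full-model residuals for the normality summary
    resid = np.concatenate(
        [
            y1 - np.polyval(np.polyfit(x1, y1, 1), x1),
            y2 - np.polyval(np.polyfit(x2, y2, 1), x2),
        ]
    )

    f_int = p_int = None
    df_int = None
    intercepts_equal = None
    if p_slope >= alpha:
        df_common = n - 3
        f_int = _f_ratio(sse_single - sse_common, sse_common / df_common)
        p_int = float(stats.f.sf(f_int, 1, df_common))
        df_int = (1, df_common)
        intercepts_equal = p_int >= alpha
    return CurveComparison(
        pigment=pigment,
        f_slope=float(f_slope),
        df_slope=(1, df_full),
        p_slope=p_slope,
        slopes_equal=p_slope >= alpha,
        f_intercept=float(f_int) if f_int is not None else None,
        df_intercept=df_int,
        p_intercept=p_int,
        intercepts_equal=intercepts_equal,
        alpha=alpha,
        n_control=int(x1.size),
        n_variable=int(x2.size),
        residual_skew=float(stats.skew(resid)),
        residual_kurtosis=float(stats.kurtosis(resid)),
    )


@dataclass
class InterferenceErrorTable:
    """Signed % error from applying the control curve under interference.

    Evaluated at the control curve's maximum and half-maximum measurable
    concentrations: the control line maps the concentration to a GPI, the
    condition ("variable") line maps that GPI back to the concentration the
    condition would actually have, and the error is expressed relative to
    that actual value.  Defined only within the control linear interval.
    """

    pigment: str
    pct_error_at_max: float
    pct_error_at_half_max: float
    max_chl: float
    half_max_chl: float

    def to_dict(self) -> dict:
        return asdict(self)


def interference_error_table(
    control_curve: CalibrationCurve, variable_curve: CalibrationCurve
) -> InterferenceErrorTable:
    if control_curve.slope <= 0:
        raise InvalidCurveError("control curve slope must be positive")
    if variable_curve.slope <= 0:
        raise InvalidCurveError("variable curve slope must be positive")
    errors = []
    levels = (control_curve.upper_limit_chl, control_curve.upper_limit_chl / 2.0)
    for c in levels:
        g = control_curve.slope * c + control_curve.intercept
        actual = (g - variable_curve.intercept) / variable_curve.slope
        errors.append(100.0 * (c - actual) / actual)
    return InterferenceErrorTable(
        pigment=control_curve.pigment,
        pct_error_at_max=float(errors[0]),
        pct_error_at_half_max=float(errors[1]),
        max_chl=levels[0],
        half_max_chl=levels[1],
    )


def ssx_of(points) -> float:
    """Sum of squared deviations of the concentrations of a dataset."""
    x, _ = _as_xy(points) if not np.isscalar(points[0]) else (np.asarray(points, float), None)
    return float(((x - x.mean()) ** 2).sum())


@dataclass
class PowerSpec:
    """Design description for the detectable-slope-difference analysis."""

    n_control: int
    n_variable: int
    ssx_control: float
    ssx_variable: float
    residual_sd: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValidationError("alpha and power must lie in (0, 1)")
        if self.ssx_control <= 0 or self.ssx_variable <= 0 or self.residual_sd <= 0:
            raise ValidationError("SSx values and residual SD must be positive")
        if self.n_control + self.n_variable <= 4:
            raise ValidationError("need n_control + n_variable > 4")


def slope_difference_power(delta_slope: float, spec: PowerSpec) -> float:
    """Power of the two-tailed slope-equality t-test at a true |Δslope|.

    SE(Δ) = residual_sd * sqrt(1/SSx_control + 1/SSx_variable), with
    n_control + n_variable - 4 degrees of freedom; the rejection
    probability comes from the noncentral t distribution.
    """
    se = spec.residual_sd * np.sqrt(1.0 / spec.ssx_control + 1.0 / spec.ssx_variable)
    df = spec.n_control + spec.n_variable - 4
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    ncp = delta_slope / se
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # scipy's noncentral-t lower tail underflows to NaN at large ncp, where
    # the true contribution is negligible
    if np.isnan(lower):
        lower = 0.0
    if np.isnan(upper):
        upper = 1.0
    return float(min(1.0, upper + lower))


def detectable_slope_difference(spec: PowerSpec) -> float:
    """Smallest |Δslope| detectable at the requested alpha and power.

    Solved by bracketed root finding on the noncentral-t power function to
    a relative tolerance well below 1e-10.  In the large-df limit this
    approaches SE(Δ) * (z_{1-alpha/2} + z_{power}).
    """
    se = spec.residual_sd * np.sqrt(1.0 / spec.ssx_control + 1.0 / spec.ssx_variable)
    df = spec.n_control + spec.n_variable - 4
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    hi = se * (tcrit + stats.norm.ppf(spec.power) + 10.0)

    def gap(delta: float) -> float:
        return slope_difference_power(delta, spec) - spec.power

    try:
        delta = optimize.brentq(gap, 0.0, hi, xtol=1e-300, rtol=1e-12, maxiter=200)
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise NumericalError(
            f"detectable-slope solve failed on [0, {hi:.3g}]: {exc}"
        ) from exc
    return float(delta)
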