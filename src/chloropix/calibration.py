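"""Standard-curve construction and analytical validation.

The assay relates the final green pixel intensity of a sample (y) to its
extraction-measured chlorophyll concentration (x, ug/ml) by ordinary least
squares over the response's linear interval.  This module provides

* the OLS fit with standard errors and R^2,
* automatic detection of the linear interval: points are removed one at a
  time starting from the highest concentration, R^2 recomputed after each
  removal for as long as it improves, and the set whose R^2 is closest to
  1.00 along that path retained (at least three points always remain),
* the pointwise 95% confidence band for the mean response,
* limit of blank and limit of detection in the mean + 1.645 SD convention,
  computed in GPI units and converted to concentration through the fitted
  line,
* assay precision as the mean percent relative standard deviation of
  back-predicted concentrations over triplicate photographs, and
* inverse prediction of concentration from a measured GPI with a status
  flag (below detection limit / within range / needs dilution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidCurveError, SingularFitError, ValidationError

__all__ = [
    "CalibrationPoint",
    "LinearFit",
    "LinearInterval",
    "CalibrationCurve",
    "Prediction",
    "fit_linear",
    "find_linear_interval",
    "confidence_band",
    "limit_of_blank",
    "limit_of_detection",
    "percent_rsd",
    "build_standard_curve",
    "predict_chlorophyll",
]

Pigment = Literal["a", "b", "total"]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration sample: mean GPI of 3 photos vs mean extracted chl."""

    sample_id: str
    chl: float
    gpi_final: float
    pigment: str = "total"
    replicate_gpis: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.chl < 0:
            raise ValidationError(f"negative chlorophyll {self.chl} for {self.sample_id}")
        if self.replicate_gpis is not None:
            reps = tuple(float(v) for v in self.replicate_gpis)
            object.__setattr__(self, "replicate_gpis", reps)
            if abs(float(np.mean(reps)) - self.gpi_final) > 1e-6:
                raise ValidationError(
                    f"replicate GPIs of {self.sample_id} do not average to gpi_final"
                )


def _xy(points: Sequence[CalibrationPoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray([p.chl for p in points], dtype=float)
    y = np.asarray([p.gpi_final for p in points], dtype=float)
    return x, y


@dataclass(frozen=True)
class LinearFit:
    """OLS summary of y = slope * x + intercept."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    residual_sd: float
    n: int
    x_mean: float
    ssx: float


def fit_linear(points: Sequence[CalibrationPoint]) -> LinearFit:
    """Ordinary least squares of GPI on chlorophyll concentration.

    Standard errors use the usual n - 2 degrees of freedom; residual_sd is
    the root mean squared error on those degrees of freedom.
    """
    if len(points) < 3:
        raise ValidationError(f"need at least 3 points to fit, got {len(points)}")
    x, y = _xy(points)
    if np.ptp(x) == 0:
        raise SingularFitError("all x values identical; slope is not identifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        r_squared=float(res.rsquared),
        residual_sd=float(np.sqrt(res.mse_resid)),
        n=len(points),
        x_mean=float(x.mean()),
        ssx=float(((x - x.mean()) ** 2).sum()),
    )


@dataclass
class LinearInterval:
    """Result of linear-interval detection."""

    points: list[CalibrationPoint]
    upper_limit_chl: float
    upper_limit_gpi: float  # observed GPI of the highest retained point
    r_squared: float
    n_dropped: int


def find_linear_interval(points: Sequence[CalibrationPoint]) -> LinearInterval:
    """Detect the linear interval by backward removal of high concentrations.

    Points are sorted by concentration and the highest-concentration point
    is removed one at a time, refitting after each removal, for as long as
    R^2 keeps improving; the retained set is the one whose R^2 is closest
    to 1.00 along that removal path.  Removal stops once it no longer
    helps, so perfectly linear data keep every point and chance-high R^2
    of tiny low-concentration subsets cannot win.  Interior points are
    never dropped (the result is always a prefix in concentration order),
    and at least three points are always retained.
    """
    if len(points) < 3:
        raise ValidationError(f"need at least 3 points, got {len(points)}")
    ordered = sorted(points, key=lambda p: p.chl)
    best_k = len(ordered)
    best_r2 = fit_linear(ordered).r_squared
    for k in range(len(ordered) - 1, 2, -1):
        r2 = fit_linear(ordered[:k]).r_squared
        if r2 <= best_r2:  # removal no longer improves the fit: stop
            break
        best_k, best_r2 = k, r2
    retained = ordered[:best_k]
    top = retained[-1]
    return LinearInterval(
        points=list(retained),
        upper_limit_chl=top.chl,
        upper_limit_gpi=top.gpi_final,
        r_squared=float(best_r2),
        n_dropped=len(ordered) - best_k,
    )


def confidence_band(
    fit: LinearFit, x_grid: Sequence[float], level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise confidence band for the mean response along ``x_grid``.

    Half-width at x is t(1 - alpha/2, n - 2) * residual_sd *
    sqrt(1/n + (x - x_mean)^2 / SSx); at the design mean this reduces to
    t * residual_sd / sqrt(n).
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.size == 0:
        raise ValidationError("empty x grid for confidence band")
    if fit.n < 3:
        raise ValidationError("confidence band requires a fit on >= 3 points")
    tcrit = stats.t.ppf(0.5 + level / 2, fit.n - 2)
    yhat = fit.slope * x_grid + fit.intercept
    half = tcrit * fit.residual_sd * np.sqrt(1.0 / fit.n + (x_grid - fit.x_mean) ** 2 / fit.ssx)
    return yhat - half, yhat + half


def limit_of_blank(blank_gpis: Sequence[float]) -> float:
    """LoB = mean(blanks) + 1.645 SD(blanks), in GPI units.

    Blanks are gpi_final readings of media-only vessels; negative readings
    are legitimate and must be included for an unbiased spread estimate.
    """
    blanks = np.asarray(blank_gpis, dtype=float)
    if blanks.size < 3:
        raise ValidationError(f"need >= 3 blank replicates, got {blanks.size}")
    return float(blanks.mean() + 1.645 * blanks.std(ddof=1))


def limit_of_detection(
    lob_gpi: float, low_conc_gpis: Sequence[float], fit: LinearFit
) -> float:
    """LoD in ug/ml: (LoB + 1.645 SD(low-concentration replicates)) through the line.

    The GPI-scale detection limit is converted to concentration by
    inverting the calibration line and flooring at zero.
    """
    low = np.asarray(low_conc_gpis, dtype=float)
    if low.size < 3:
        raise ValidationError(f"need >= 3 low-concentration replicates, got {low.size}")
    if fit.slope <= 0:
        raise InvalidCurveError(f"slope {fit.slope} is not positive; cannot invert")
    lod_gpi = lob_gpi + 1.645 * low.std(ddof=1)
    return max(0.0, (lod_gpi - fit.intercept) / fit.slope)


def percent_rsd(
    points: Sequence[CalibrationPoint],
    fit: LinearFit,
    upper_limit_chl: float | None = None,
) -> float:
    """Mean %RSD of back-predicted concentrations over triplicate photos.

    For each in-interval point carrying per-photo replicate GPIs, each
    replicate is inverted through the line and 100 * SD / mean of the three
    predictions computed; the unweighted mean across points is returned.
    Points whose mean prediction is not positive are excluded with a
    warning (the ratio is undefined there).
    """
    import warnings

    if fit.slope <= 0:
        raise InvalidCurveError(f"slope {fit.slope} is not positive; cannot invert")
    rsds = []
    for p in points:
        if p.replicate_gpis is None:
            continue
        if upper_limit_chl is not None and p.chl > upper_limit_chl:
            continue
        preds = (np.asarray(p.replicate_gpis) - fit.intercept) / fit.slope
        mean = preds.mean()
        if mean <= 0:
            warnings.warn(
                f"sample {p.sample_id}: mean back-predicted concentration "
                f"{mean:.3g} <= 0; excluded from %RSD",
                stacklevel=2,
            )
            continue
        rsds.append(100.0 * preds.std(ddof=1) / mean)
    if not rsds:
        raise ValidationError("no usable replicate sets for %RSD")
    return float(np.mean(rsds))


@dataclass
class CalibrationCurve:
    """A fitted standard curve with its analytical characteristics.

    Slope is in GPI per (ug/ml); concentrations in ug/ml of culture.
    ``upper_limit_gpi`` is the fitted response at the upper limit of the
    linear interval, the threshold above which samples must be diluted.
    Fields that require blank/replicate data are None when built directly
    from published coefficients.
    """

    pigment: str
    slope: float
    intercept: float
    upper_limit_chl: float
    upper_limit_gpi: float
    slope_se: float | None = None
    intercept_se: float | None = None
    r_squared: float | None = None
    residual_sd: float | None = None
    n_points: int | None = None
    lob_gpi: float | None = None
    lob_conc: float | None = None
    lod_conc: float | None = None
    percent_rsd: float | None = None
    x_mean: float | None = None
    ssx: float | None = None

    @classmethod
    def from_line(
        cls,
        slope: float,
        intercept: float,
        upper_limit_chl: float,
        pigment: str = "total",
    ) -> "CalibrationCurve":
        """Build a bare curve from published slope/intercept coefficients."""
        return cls(
            pigment=pigment,
            slope=slope,
            intercept=intercept,
            upper_limit_chl=upper_limit_chl,
            upper_limit_gpi=slope * upper_limit_chl + intercept,
        )

    def fit_view(self) -> LinearFit:
        if self.n_points is None or self.x_mean is None:
            raise ValidationError("curve lacks full fit information")
        return LinearFit(
            slope=self.slope,
            intercept=self.intercept,
            slope_se=self.slope_se,
            intercept_se=self.intercept_se,
            r_squared=self.r_squared,
            residual_sd=self.residual_sd,
            n=self.n_points,
            x_mean=self.x_mean,
            ssx=self.ssx,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def build_standard_curve(
    points: Sequence[CalibrationPoint],
    blanks: Sequence[float],
    low_conc_gpis: Sequence[float] | None = None,
    pigment: str = "total",
) -> CalibrationCurve:
    """Full calibration for one pigment.

    Runs linear-interval detection, fits the retained points, computes LoB
    from the blank replicates, LoD from low-concentration replicates (by
    default the per-photo GPIs of the lowest-concentration retained point
    that carries them; the blanks themselves otherwise) and the mean %RSD
    over in-interval triplicates.
    """
    interval = find_linear_interval(points)
    fit = fit_linear(interval.points)
    lob_gpi = limit_of_blank(blanks)
    if low_conc_gpis is None:
        with_reps = [p for p in interval.points if p.replicate_gpis is not None and p.chl > 0]
        if with_reps:
            low_conc_gpis = min(with_reps, key=lambda p: p.chl).replicate_gpis
        else:
            low_conc_gpis = blanks
    if fit.slope <= 0:
        raise InvalidCurveError(f"fitted slope {fit.slope} is not positive")
    lod_conc = limit_of_detection(lob_gpi, low_conc_gpis, fit)
    lob_conc = max(0.0, (lob_gpi - fit.intercept) / fit.slope)
    try:
        rsd = percent_rsd(points, fit, upper_limit_chl=interval.upper_limit_chl)
    except ValidationError:
        rsd = None  # no replicate GPIs supplied
    return CalibrationCurve(
        pigment=pigment,
        slope=fit.slope,
        intercept=fit.intercept,
        slope_se=fit.slope_se,
        intercept_se=fit.intercept_se,
        r_squared=fit.r_squared,
        residual_sd=fit.residual_sd,
        n_points=fit.n,
        upper_limit_chl=interval.upper_limit_chl,
        upper_limit_gpi=fit.slope * interval.upper_limit_chl + fit.intercept,
        lob_gpi=lob_gpi,
        lob_conc=lob_conc,
        lod_conc=lod_conc,
        percent_rsd=rsd,
        x_mean=fit.x_mean,
        ssx=fit.ssx,
    )


@dataclass(frozen=True)
class Prediction:
    """Inverse-predicted concentration with its range status."""

    concentration: float
    status: str  # "ok" | "below_LoD" | "dilute_sample"


def predict_chlorophyll(curve: CalibrationCurve, gpi_final: float) -> Prediction:
    """Invert the standard curve at a measured GPI.

    The concentration is always reported; the status flags readings above
    the linear interval (dilute and re-photograph) or below the detection
    limit (when the curve carries one; otherwise below zero).
    """
    if curve.slope <= 0:
        raise InvalidCurveError(f"slope {curve.slope} is not positive; cannot invert")
    conc = (gpi_final - curve.intercept) / curve.slope
    lod = curve.lod_conc if curve.lod_conc is not None else 0.0
    if gpi_final > curve.upper_limit_gpi:
        status = "dilute_sample"
    elif conc < lod:
        status = "below_LoD"
    else:
        status = "ok"
    return Prediction(concentration=float(conc), status=status)
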