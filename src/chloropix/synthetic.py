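"""Synthetic assay data and rendered flask photographs with ground truth.

Two generators make every stage of the pipeline testable without any real
photographs:

* :func:`simulate_calibration_dataset` draws calibration points from a
  linear-then-saturating mean response.  Below the breakpoint the mean GPI
  is ``slope * chl + intercept``; above it the response approaches a
  plateau along an exponential whose initial slope matches the line, so
  the curve is continuous with a continuous first derivative.  Each of the
  three photographs per sample receives independent Gaussian GPI noise, and
  a shared triplicate baseline (media-only vessel) is subtracted, exactly
  as in the real protocol.  Blank (zero-chlorophyll) samples for the
  limit-of-blank are generated the same way.

* :func:`render_flask_image` paints a small white-background photograph of
  a culture vessel.  The culture region attenuates the background color
  channel-wise by ``exp(-extinction * chl)``, with the green extinction
  smallest so that the green pixel intensity rises with pigment; a shadow
  stripe is darkened by a constant factor (which leaves the GPI ratio
  unchanged); Gaussian pixel noise is added before 8-bit quantization.
  The noise-free culture GPI is returned as ground truth together with a
  matching annotation, so image extraction can be scored end to end.

* :func:`simulate_null_comparison` calibrates the curve-comparison tests:
  it draws many paired datasets from one true line (optionally with an
  injected slope difference) and reports rejection rates with confidence
  intervals.

Default assay parameters mirror the study conditions the package targets:
slope 0.00694 GPI per (ug/ml), zero intercept, linearity up to 16 ug/ml
with the response at the breakpoint close below the plateau, and per-photo
GPI noise of 0.002, which puts mid-curve replicate scatter on the scale of
the assay's reported precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .calibration import CalibrationPoint
from .comparison import compare_curves
from .errors import ValidationError
from .image_gpi import PhotoAnnotation

__all__ = [
    "AssayConfig",
    "RenderConfig",
    "SimulatedAssay",
    "RenderedPhoto",
    "NullComparisonSummary",
    "mean_response",
    "simulate_calibration_dataset",
    "render_flask_image",
    "simulate_null_comparison",
]


def _default_grid() -> tuple[float, ...]:
    return tuple(np.linspace(0.1, 25.0, 25))


@dataclass
class AssayConfig:
    """True parameters of a simulated GPI-vs-chlorophyll assay."""

    true_slope: float = 0.00694  # GPI per (ug/ml)
    true_intercept: float = 0.0
    noise_sd_gpi: float = 0.002  # per-photo GPI noise
    breakpoint_chl: float = 16.0  # ug/ml, start of saturation
    plateau_gpi: float = 0.125  # asymptotic GPI at high chlorophyll
    conc_grid: tuple[float, ...] = field(default_factory=_default_grid)
    photos_per_sample: int = 3
    n_blanks: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_slope <= 0:
            raise ValidationError("true_slope must be positive")
        if self.noise_sd_gpi < 0:
            raise ValidationError("noise_sd_gpi must be non-negative")
        grid = tuple(float(c) for c in self.conc_grid)
        if not grid or min(grid) < 0:
            raise ValidationError("conc_grid must be non-empty and non-negative")
        if not (min(grid) <= self.breakpoint_chl <= max(grid)):
            raise ValidationError("breakpoint_chl must lie within the concentration grid")
        y_bp = self.true_slope * self.breakpoint_chl + self.true_intercept
        if self.plateau_gpi <= y_bp:
            raise ValidationError("plateau_gpi must exceed the response at the breakpoint")
        self.conc_grid = grid


def mean_response(chl, config: AssayConfig):
    """Noise-free mean GPI at concentration(s) ``chl``.

    Linear up to the breakpoint, then an exponential approach to the
    plateau with a slope-matched (C1) junction.
    """
    chl = np.asarray(chl, dtype=float)
    linear = config.true_slope * chl + config.true_intercept
    y_bp = config.true_slope * config.breakpoint_chl + config.true_intercept
    gap = config.plateau_gpi - y_bp
    sat = y_bp + gap * (
        1.0 - np.exp(-config.true_slope * (chl - config.breakpoint_chl) / gap)
    )
    out = np.where(chl <= config.breakpoint_chl, linear, sat)
    return float(out) if out.ndim == 0 else out


@dataclass
class SimulatedAssay:
    """A simulated calibration dataset plus its ground truth."""

    points: list[CalibrationPoint]
    blanks: list[float]
    truth: dict


def simulate_calibration_dataset(
    config: AssayConfig, pigment: str = "total"
) -> SimulatedAssay:
    """Draw one calibration dataset under ``config`` (seed-deterministic).

    Each sample's three per-photo GPI readings get independent
    N(0, noise_sd^2) noise around the mean response, and the mean of a
    shared three-photo baseline is subtracted from every sample and blank,
    as in the real workflow.  Replicate GPIs are stored per point so %RSD
    is computable downstream.
    """
    rng = np.random.default_rng(config.seed)
    k = config.photos_per_sample
    baseline_mean = float(rng.normal(0.0, config.noise_sd_gpi, k).mean())
    points = []
    for i, chl in enumerate(config.conc_grid):
        mu = mean_response(chl, config)
        reps = mu + rng.normal(0.0, config.noise_sd_gpi, k) - baseline_mean
        points.append(
            CalibrationPoint(
                sample_id=f"S{i + 1:02d}",
                chl=float(chl),
                gpi_final=float(reps.mean()),
                pigment=pigment,
                replicate_gpis=tuple(float(v) for v in reps),
            )
        )
    blanks = [
        float(rng.normal(0.0, config.noise_sd_gpi, k).mean() - baseline_mean)
        for _ in range(config.n_blanks)
    ]
    truth = {
        "true_slope": config.true_slope,
        "true_intercept": config.true_intercept,
        "breakpoint_chl": config.breakpoint_chl,
        "plateau_gpi": config.plateau_gpi,
        "noise_sd_gpi": config.noise_sd_gpi,
        "baseline_mean": baseline_mean,
        "mean_response": {
            f"{c:g}": mean_response(c, config) for c in config.conc_grid
        },
        "seed": config.seed,
    }
    return SimulatedAssay(points=points, blanks=blanks, truth=truth)


def _default_geometry() -> dict[str, list[int]]:
    return {
        "culture_shadow": [20, 30, 28, 50],
        "culture_lit": [28, 30, 50, 50],
        "background_left": [20, 5, 50, 15],
        "background_right": [20, 65, 50, 75],
    }


@dataclass
class RenderConfig:
    """Parameters of the toy flask renderer."""

    image_size: tuple[int, int] = (60, 80)  # (rows, cols)
    background_rgb: tuple[float, float, float] = (250.0, 250.0, 252.0)
    shadow_attenuation: float = 0.85
    # per-channel attenuation per (ug/ml); green smallest so GPI rises with chl
    channel_extinctions: tuple[float, float, float] = (0.035, 0.012, 0.030)
    vessel_geometry: dict = field(default_factory=_default_geometry)
    pixel_noise_sd: float = 2.0  # 8-bit units
    seed: int = 0

    def __post_init__(self) -> None:
        er, eg, eb = self.channel_extinctions
        if not (eg < er and eg < eb):
            raise ValidationError(
                "green extinction must be smaller than red and blue "
                "(otherwise GPI would not rise with chlorophyll)"
            )
        if min(self.background_rgb) < 200:
            raise ValidationError("background must be near-white (channels >= 200)")
        h, w = self.image_size
        for name, (r0, c0, r1, c1) in self.vessel_geometry.items():
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w or r1 <= r0 or c1 <= c0:
                raise ValidationError(
                    f"region {name!r} {[r0, c0, r1, c1]} outside {h}x{w} image"
                )


@dataclass
class RenderedPhoto:
    """One rendered photograph with its annotation and ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    annotation: PhotoAnnotation
    truth: dict  # noise-free culture/background GPI and their difference


def render_flask_image(
    chl_total: float,
    config: RenderConfig,
    rng: np.random.Generator | None = None,
    role: str = "sample",
    sample_id: str = "sample",
) -> RenderedPhoto:
    """Render one flask photograph at a given total chlorophyll.

    Ground truth (pre-noise, pre-quantization): the culture GPI of the lit
    region, the background GPI, and their difference — the quantity the
    extraction pipeline estimates for a single photograph.
    """
    if chl_total < 0:
        raise ValidationError(f"chlorophyll must be non-negative, got {chl_total}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    h, w = config.image_size
    bg = np.asarray(config.background_rgb, dtype=float)
    ext = np.asarray(config.channel_extinctions, dtype=float)
    culture = bg * np.exp(-ext * chl_total)

    canvas = np.broadcast_to(bg, (h, w, 3)).copy()
    geo = config.vessel_geometry
    for name in ("culture_lit", "culture_shadow"):
        r0, c0, r1, c1 = geo[name]
        canvas[r0:r1, c0:c1] = culture
    r0, c0, r1, c1 = geo["culture_shadow"]
    canvas[r0:r1, c0:c1] *= config.shadow_attenuation

    noisy = canvas + rng.normal(0.0, config.pixel_noise_sd, canvas.shape)
    image = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    culture_gpi = float(culture[1] / culture.sum())
    background_gpi = float(bg[1] / bg.sum())
    annotation = PhotoAnnotation(
        image_path=None,
        culture_shadow_region=list(geo["culture_shadow"]),
        culture_lit_region=list(geo["culture_lit"]),
        background_left_region=list(geo["background_left"]),
        background_right_region=list(geo["background_right"]),
        role=role,
        sample_id=sample_id,
    )
    return RenderedPhoto(
        image=image,
        annotation=annotation,
        truth={
            "chl_total": float(chl_total),
            "culture_gpi": culture_gpi,
            "background_gpi": background_gpi,
            "gpi_sample": culture_gpi - background_gpi,
        },
    )


@dataclass
class NullComparisonSummary:
    """Rejection rates of the curve-comparison tests over many replicates."""

    replicates: int
    alpha: float
    delta_slope: float
    slope_rejection_rate: float
    slope_rate_ci: tuple[float, float]
    intercept_tests_run: int
    intercept_rejection_rate: float | None
    intercept_rate_ci: tuple[float, float] | None

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_null_comparison(
    n_per_group: int,
    curve_params: tuple[float, float] = (0.00694, 0.0),
    noise_sd: float = 0.002,
    replicates: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    x_max: float = 16.0,
    delta_slope: float = 0.0,
) -> NullComparisonSummary:
    """Monte Carlo calibration of :func:`compare_curves`.

    Both groups share the concentration design (an even grid on
    [0.5, x_max]) and the true line; group two's slope is offset by
    ``delta_slope`` (zero for a type-I-error run).  The intercept test only
    runs on replicates where the slope test does not reject, so its rate is
    conditional on that event.  Wilson 95% intervals accompany both rates.
    """
    if replicates < 100:
        raise ValidationError("need at least 100 replicates for stable rates")
    slope, intercept = curve_params
    x = np.linspace(0.5, x_max, n_per_group)
    rng = np.random.default_rng(seed)
    slope_rej = 0
    int_tests = 0
    int_rej = 0
    for _ in range(replicates):
        y1 = intercept + slope * x + rng.normal(0.0, noise_sd, n_per_group)
        y2 = intercept + (slope + delta_slope) * x + rng.normal(0.0, noise_sd, n_per_group)
        cmp_ = compare_curves((x, y1), (x, y2), alpha=alpha)
        if cmp_.p_slope < alpha:
            slope_rej += 1
        elif cmp_.p_intercept is not None:
            int_tests += 1
            if cmp_.p_intercept < alpha:
                int_rej += 1
    lo, hi = proportion_confint(slope_rej, replicates, alpha=0.05, method="wilson")
    if int_tests:
        ilo, ihi = proportion_confint(int_rej, int_tests, alpha=0.05, method="wilson")
        int_rate: float | None = int_rej / int_tests
        int_ci: tuple[float, float] | None = (float(ilo), float(ihi))
    else:
        int_rate, int_ci = None, None
    return NullComparisonSummary(
        replicates=replicates,
        alpha=alpha,
        delta_slope=delta_slope,
        slope_rejection_rate=slope_rej / replicates,
        slope_rate_ci=(float(lo), float(hi)),
        intercept_tests_run=int_tests,
        intercept_rejection_rate=int_rate,
        intercept_rate_ci=int_ci,
    )
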