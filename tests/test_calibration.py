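"""Standard-curve fitting, linear-interval detection, LoB/LoD, precision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chloropix.calibration import (
    CalibrationCurve,
    CalibrationPoint,
    build_standard_curve,
    confidence_band,
    find_linear_interval,
    fit_linear,
    limit_of_blank,
    limit_of_detection,
    percent_rsd,
    predict_chlorophyll,
)
from chloropix.errors import InvalidCurveError, SingularFitError, ValidationError
from chloropix.synthetic import AssayConfig, mean_response, simulate_calibration_dataset


def _points(x, y, reps=None):
    return [
        CalibrationPoint(
            sample_id=f"P{i}",
            chl=float(xi),
            gpi_final=float(yi),
            replicate_gpis=None if reps is None else tuple(reps[i]),
        )
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


from tests_support_oracles import brute_force_line


def test_exact_line_recovered():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    fit = fit_linear(_points(x, 2 * x + 1))
    assert fit.slope == pytest.approx(2.0, abs=1e-10)
    assert fit.intercept == pytest.approx(1.0, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fit_matches_brute_force_sse_minimizer():
    rng = np.random.default_rng(5)
    for _ in range(5):
        n = rng.integers(4, 11)
        x = rng.uniform(0, 5, n)
        y = rng.uniform(-2, 2) * x + rng.uniform(-1, 1) + rng.normal(0, 0.3, n)
        fit = fit_linear(_points(x, y))
        slope, intercept = brute_force_line(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-6)
        assert fit.intercept == pytest.approx(intercept, abs=1e-6)


def test_degenerate_x_raises():
    with pytest.raises(SingularFitError):
        fit_linear(_points([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]))
    with pytest.raises(ValidationError):
        fit_linear(_points([0.0, 1.0], [0.0, 1.0]))


def test_linear_interval_keeps_all_points_when_linear():
    x = np.linspace(0, 10, 12)
    interval = find_linear_interval(_points(x, 0.01 * x + 0.002))
    assert len(interval.points) == 12
    assert interval.upper_limit_chl == pytest.approx(10.0)
    assert interval.n_dropped == 0


def test_linear_interval_drops_saturated_points_noise_free():
    config = AssayConfig(noise_sd_gpi=0.0, seed=0)
    assay = simulate_calibration_dataset(config)
    interval = find_linear_interval(assay.points)
    retained = max(p.chl for p in interval.points)
    assert retained <= config.breakpoint_chl
    # everything at or below the breakpoint is genuinely linear, so the
    # detector must not cut deep into the linear range
    grid = np.asarray(config.conc_grid)
    last_linear = grid[grid <= config.breakpoint_chl].max()
    assert retained == pytest.approx(last_linear)


def test_linear_interval_is_a_prefix():
    rng = np.random.default_rng(1)
    x = np.linspace(0.5, 20, 15)
    y = np.minimum(0.007 * x, 0.09) + rng.normal(0, 0.001, x.size)
    interval = find_linear_interval(_points(x, y))
    kept = sorted(p.chl for p in interval.points)
    assert kept == [float(v) for v in x[: len(kept)]]
    assert len(kept) >= 3


def test_confidence_band_center_and_monotone_width():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    rng = np.random.default_rng(2)
    y = 0.5 * x + 0.1 + rng.normal(0, 0.05, 5)
    fit = fit_linear(_points(x, y))
    lower, upper = confidence_band(fit, [fit.x_mean])
    tcrit = stats.t.ppf(0.975, 3)
    assert (upper[0] - lower[0]) / 2 == pytest.approx(
        tcrit * fit.residual_sd / np.sqrt(5), rel=1e-12
    )
    grid = np.linspace(-5, 15, 41)
    lo, hi = confidence_band(fit, grid)
    width = hi - lo
    d_from_mean = np.abs(grid - fit.x_mean)
    order = np.argsort(d_from_mean)
    assert (np.diff(width[order]) >= -1e-12).all()
    # oracle: direct formula evaluation at a few x values
    for xv in (0.0, 2.5, 9.0):
        half = tcrit * fit.residual_sd * np.sqrt(1 / 5 + (xv - fit.x_mean) ** 2 / fit.ssx)
        lo1, hi1 = confidence_band(fit, [xv])
        assert hi1[0] - (fit.slope * xv + fit.intercept) == pytest.approx(half, rel=1e-12)
    with pytest.raises(ValidationError):
        confidence_band(fit, [])


def test_limit_of_blank_hand_values():
    assert limit_of_blank([0.0, 0.0, 0.0]) == 0.0
    blanks = [0.0, 0.001, -0.001, 0.002, -0.002]
    sd = np.std(blanks, ddof=1)
    assert sd == pytest.approx(0.001581, abs=1e-6)
    assert limit_of_blank(blanks) == pytest.approx(0.002601, abs=1e-6)
    with pytest.raises(ValidationError):
        limit_of_blank([0.0, 0.001])


def test_limit_of_detection_hand_value_and_floor():
    fit = fit_linear(_points([0, 5, 10, 16], [0.0, 0.0347, 0.0694, 0.11104]))
    assert fit.slope == pytest.approx(0.00694, rel=1e-6)
    lod = limit_of_detection(0.0026, [0.001, 0.002, 0.003], fit)
    # (0.0026 + 1.645 * 0.001) / 0.00694
    assert lod == pytest.approx((0.0026 + 0.001645) / 0.00694, rel=1e-6)
    assert lod == pytest.approx(0.612, abs=1e-3)
    # degenerate: zero-variance replicates, zero LoB, zero intercept -> floored at 0
    assert limit_of_detection(0.0, [0.001, 0.001, 0.001], fit) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(InvalidCurveError):
        limit_of_detection(0.0, [0.001, 0.002, 0.003], fit_linear(_points([0, 1, 2], [0.2, 0.1, 0.0])))


def test_lod_recovery_at_paper_scale():
    """Simulated assay whose true LoD is 0.12 ug/ml recovers it within 25%.

    True LoD = (1.645 + 1.645) * sd_final / slope with zero intercept, so a
    per-reading SD of 0.12 * slope / 3.29 makes the truth exactly 0.12.
    """
    slope = 0.00694
    sd_final = 0.12 * slope / 3.29
    rng = np.random.default_rng(314)
    lods = []
    for _ in range(200):
        blanks = rng.normal(0.0, sd_final, 10)
        low = rng.normal(0.12 * slope, sd_final, 10)
        fit_stub = fit_linear(
            _points([0, 5, 10, 16], np.array([0, 5, 10, 16]) * slope)
        )
        lods.append(limit_of_detection(limit_of_blank(blanks), low, fit_stub))
    assert np.mean(lods) == pytest.approx(0.12, rel=0.25)


def test_percent_rsd_hand_values():
    fit = fit_linear(_points([0, 5, 10], [0.0, 5.0, 10.0]))  # identity line
    pts = _points([10.0], [10.0], reps=[(9.5, 10.0, 10.5)])
    assert percent_rsd(pts, fit) == pytest.approx(5.0, rel=1e-9)
    same = _points([10.0], [10.0], reps=[(10.0, 10.0, 10.0)])
    assert percent_rsd(same, fit) == 0.0
    neg = _points([0.0], [-1.0], reps=[(-1.0, -1.0, -1.0)])
    with pytest.warns(UserWarning, match="excluded"):
        with pytest.raises(ValidationError):
            percent_rsd(neg, fit)


def test_build_standard_curve_noise_free():
    config = AssayConfig(noise_sd_gpi=0.0, seed=0)
    assay = simulate_calibration_dataset(config)
    curve = build_standard_curve(assay.points, blanks=[0.0, 0.0, 0.0, 0.0])
    assert curve.r_squared == pytest.approx(1.0, abs=1e-9)
    assert curve.slope == pytest.approx(config.true_slope, rel=1e-9)
    assert curve.percent_rsd == pytest.approx(0.0, abs=1e-9)
    assert curve.lod_conc >= curve.lob_conc >= 0.0
    assert curve.upper_limit_gpi == pytest.approx(
        curve.slope * curve.upper_limit_chl + curve.intercept, abs=1e-12
    )


def test_build_standard_curve_orders_limits(simulated_assay):
    curve = build_standard_curve(simulated_assay.points, simulated_assay.blanks)
    assert 0.0 <= curve.lob_conc <= curve.lod_conc
    assert curve.n_points >= 3
    assert 0.0 <= curve.r_squared <= 1.0


@settings(derandomize=True, max_examples=50)
@given(x=st.floats(0.0, 30.0))
def test_predict_inverts_forward_line(x):
    curve = CalibrationCurve.from_line(0.00694, 0.000799, upper_limit_chl=16.0)
    gpi = curve.slope * x + curve.intercept
    assert predict_chlorophyll(curve, gpi).concentration == pytest.approx(x, abs=1e-9)


def test_predict_status_flags():
    curve = CalibrationCurve.from_line(0.00694, 0.000799, upper_limit_chl=16.0)
    curve.lod_conc = 0.12
    pred = predict_chlorophyll(curve, 0.0702)
    assert pred.concentration == pytest.approx(10.00, abs=0.01)
    assert pred.status == "ok"
    assert predict_chlorophyll(curve, curve.intercept).status == "below_LoD"
    assert predict_chlorophyll(curve, 0.126).status == "dilute_sample"
    bad = CalibrationCurve.from_line(0.00694, 0.0, 16.0)
    bad.slope = -1.0
    with pytest.raises(InvalidCurveError):
        predict_chlorophyll(bad, 0.1)


def test_replicate_mean_must_match_gpi_final():
    with pytest.raises(ValidationError):
        CalibrationPoint("S1", 1.0, 0.01, replicate_gpis=(0.5, 0.5, 0.5))
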