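"""Build a standard curve from a simulated assay and predict new samples.

Simulates triplicate-photograph calibration data with a known linear range
(slope 0.00694 GPI per ug/ml, saturating past 16 ug/ml), detects the
linear interval, fits the curve with its analytical characteristics, and
inverse-predicts chlorophyll for three new GPI readings.
"""

import numpy as np

from chloropix import (
    AssayConfig,
    build_standard_curve,
    confidence_band,
    predict_chlorophyll,
    simulate_calibration_dataset,
)

assay = simulate_calibration_dataset(AssayConfig(seed=42))
curve = build_standard_curve(assay.points, assay.blanks)

print(f"fitted line     : GPI = {curve.slope:.5f} * chl + {curve.intercept:.6f}")
print(f"R^2             : {curve.r_squared:.4f}  (n = {curve.n_points} in-interval points)")
print(f"linear interval : up to {curve.upper_limit_chl:.2f} ug/ml (GPI {curve.upper_limit_gpi:.4f})")
print(f"LoB / LoD       : {curve.lob_conc:.3f} / {curve.lod_conc:.3f} ug/ml")
print(f"true slope      : {assay.truth['true_slope']:.5f} (simulation ground truth)")

band_lo, band_hi = confidence_band(curve.fit_view(), [8.0])
print(f"95% band at 8 ug/ml: GPI in [{band_lo[0]:.5f}, {band_hi[0]:.5f}]")

print("\ninverse predictions:")
for gpi in (0.0005, 0.0702, 0.1400):
    pred = predict_chlorophyll(curve, gpi)
    print(f"  GPI {gpi:.4f} -> {pred.concentration:7.3f} ug/ml  [{pred.status}]")
print(
    "\nA reading below the detection limit is flagged below_LoD; one above the"
    "\nlinear interval is flagged dilute_sample (dilute and re-photograph)."
)
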