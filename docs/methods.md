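# Methods

## The assay model

A culture of a green microalga photographed against a white background has
a color dominated by chlorophylls a and b. For an 8-bit RGB pixel the
green pixel intensity

    GPI = G / (R + G + B)

is a dimensionless fraction in [0, 1] (1/3 for any achromatic pixel,
exactly 1 for pure green, 0 when the green channel is empty) and is
invariant under uniform scaling of the three channels, which makes it
robust to overall illumination changes. Per photograph, three culture
pixels (spanning the lit and lid-shadowed parts of the vessel) and six
white-background pixels (three per side) are averaged and differenced:

    GPI_sample = mean GPI_culture − mean GPI_background.

Each sample is photographed three times, and a media-only baseline vessel
is photographed the same way on each sampling day:

    GPI_final = mean GPI_sample − mean GPI_baseline.

GPI_final is calibrated against chlorophyll concentrations measured by the
reference method — solvent extraction in 80% (v/v) acetone / 20% methanol
with absorbances at 663.6 and 646.6 nm, each corrected by the 750 nm
turbidity reading:

    Chl a     = (12.25 E663.6 −  2.55 E646.6) · V_extract / V_culture   [µg/ml]
    Chl b     = (20.31 E646.6 −  4.91 E663.6) · V_extract / V_culture
    Chl a + b = (17.76 E646.6 +  7.34 E663.6) · V_extract / V_culture

The total-chlorophyll coefficients are the exact sums of the a and b
coefficients, so `chl_total == chl_a + chl_b` is an algebraic identity the
tests enforce to 1e-9. The 2×2 extinction system has determinant 236.277
and is never singular; its exact inverse generates absorbance fixtures
from target concentrations. The published equations divide only by
"sample volume"; we parameterize the extract volume explicitly and default
it to 1 ml so the printed form is the default behavior. Absorbances at or
above 1.00 produce a "dilute the extract" warning but are still computed.

## Calibration and analytical validation

The standard curve is ordinary least squares of GPI_final (y) on
chlorophyll concentration (x), fitted only over the response's linear
interval. The response saturates at high pigment loads, so the linear
interval is detected by backward removal: points are sorted by
concentration and the highest-concentration point is removed one at a
time, refitting after each removal for as long as R² improves; the
retained set is the one with R² closest to 1.00 along that path. Stopping
once removal no longer helps is essential: scanning every possible
truncation all the way down to three points lets tiny low-concentration
subsets win on chance-high R² (in simulation this mislocates the upper
limit in roughly one run in five and drags slope-CI coverage below
nominal), whereas the sequential rule keeps the detection anchored to the
saturation boundary. The result is always a prefix in concentration order
with at least three points, so no interior point is ever dropped.

Analytical characteristics follow the standard clinical-chemistry
conventions:

* **LoB** = mean + 1.645·SD of blank (media-only) GPI_final replicates,
  computed in GPI units. Negative blank readings are retained — flooring
  them would bias the SD and therefore the LoB.
* **LoD** = LoB + 1.645·SD of low-concentration replicates, converted to
  µg/ml through the fitted line, floored at zero. When no explicit
  low-concentration replicate set is given, the per-photo GPIs of the
  lowest-concentration retained calibration point are used, falling back
  to the blanks.
* **Precision** is the unweighted mean, over in-interval samples, of the
  percent relative standard deviation of concentrations back-predicted
  from each of the three per-photo GPIs. Samples whose mean back-predicted
  concentration is not positive are excluded with a warning (the ratio is
  undefined there). Note that with additive GPI noise the relative SD of
  near-LoD samples is intrinsically large, so this unweighted mean is
  dominated by the low end of the curve when such samples carry
  replicates.
* The **95% confidence band** for the mean response is the pointwise
  t-based band ŷ(x) ± t(0.975, n−2) · s · sqrt(1/n + (x−x̄)²/SSx); at x̄ it
  reduces to t·s/√n and widens monotonically with |x − x̄|.

Inverse prediction divides out the line, (GPI − intercept)/slope, and
flags readings above the linear interval (`dilute_sample`: the response is
saturating, so the value underestimates the truth) or below the detection
limit (`below_LoD`). The value is always reported alongside the flag.

## Condition comparison

Whether one standard curve transfers across an environmental condition is
decided by an ANCOVA-style general linear model on the two point sets,
restricted to the control curve's linear interval (points whose GPI
exceeds the control upper-limit GPI are excluded first). The full model
fits separate slopes and intercepts; the slope test is the F-test of the
group-by-concentration interaction, F(1, n−4) from the nested-model extra
sum of squares. Only when the slope test is not significant is the
interaction dropped and the group term tested, F(1, n−3) — intercepts are
not comparable between lines of different slope. The implementation uses
closed-form within-group centered sums (exact, and fast enough for
Monte Carlo calibration); the tests verify it against an independent
statsmodels formula-OLS / anova_lm route and against design-matrix
least-squares SSE assembly to 1e-8. When a model fits exactly, the
centered-sum subtractions leave float dust at the 1e-16 relative scale;
sums of squares below 1e-12 of the total variation are treated as zero so
identical groups give F = 0, p = 1 rather than a 0/0. Residual normality
is summarized (skewness, excess kurtosis of full-model residuals) but not
enforced, matching the visual Q-Q inspection such analyses typically use.

The practical cost of ignoring a condition shift is the interference
error: for the control curve's maximum and half-maximum measurable
concentrations c, the control line maps c to a GPI, the condition line
maps that GPI back to the concentration the condition would truly have,
and the signed error 100·(c − actual)/actual is reported. With zero
intercepts the error is concentration-independent and exchanging the
curves inverts the recovery ratio exactly ((1+e₁₂/100)(1+e₂₁/100)=1);
with unequal intercepts neither property holds, which is why both levels
are tabulated.

The sensitivity power analysis answers "what slope difference could this
design have detected?": with SE(Δ) = s·sqrt(1/SSx₁ + 1/SSx₂) and
df = n₁+n₂−4, the smallest |Δslope| whose two-tailed noncentral-t
rejection probability reaches the requested power (default α = 0.05,
power = 0.80) is found by bracketed root finding (brentq, relative
tolerance 1e-12). In the large-df limit the solution approaches
SE·(z₀.₉₇₅+z₀.₈₀) ≈ 2.802·SE, which the tests check to 1%. scipy's
noncentral-t lower tail underflows to NaN at large noncentrality; the
power function replaces that term with zero, its true magnitude there
being far below any tolerance used.

## Synthetic data: what it emulates and what it does not

The assay simulator draws calibration datasets from a linear-then-
saturating mean response: linear at `true_slope`·c + `true_intercept` up
to `breakpoint_chl`, then an exponential approach to `plateau_gpi` whose
initial slope matches the line (C¹ junction). Defaults are the package's
reference conditions: slope 0.00694 GPI/(µg/ml), zero intercept, noise SD
0.002 GPI per photograph, 25 concentrations evenly spaced on 0.1–25
µg/ml, breakpoint 16 µg/ml, plateau 0.125 GPI — the plateau sits close
above the breakpoint response because the real response visibly flattens
just past the upper limit of the linear interval. Each sample's three
photographs receive independent Gaussian noise, a shared triplicate
baseline is subtracted from every sample (as in the real per-day
workflow), and media-only blanks are generated the same way for LoB work.
Generators are seed-deterministic and return ground-truth records
sufficient to score every downstream estimate.

The flask renderer paints a white background, attenuates the culture
rectangle channel-wise by exp(−extinction·chl) with the green extinction
smallest (so GPI rises with pigment), darkens a shadow stripe by a
constant factor (which leaves the GPI ratio invariant, so shadow-stratified
sampling is unbiased), adds Gaussian pixel noise, and quantizes to 8 bits.
Ground truth (noise-free, pre-quantization culture and background GPI) is
emitted with a matching annotation. Default images are 60×80 px — large
enough for the 3+6-pixel sampling protocol, small enough that end-to-end
tests render ~80 images in seconds.

These generators do **not** model: lens vignetting or white-balance error,
non-uniform illumination, turbidity from contaminants, the yellowing of
nitrogen-starved lipid-accumulating cultures, or heteroscedastic reading
noise (real blank replicates are much tighter than mid-curve replicates —
the published detection limits imply blank-level reading SD an order of
magnitude below what the mid-curve precision implies). Passing tests
therefore show the pipeline's arithmetic and statistics are correct under
a faithful idealization, not that a specific camera setup will achieve any
particular LoD.

## Numerical and design choices

* Pixel selection is seeded stratified random sampling from the annotated
  regions (2 culture pixels from the larger of shadow/lit, 1 from the
  smaller, ties favoring lit; 3 background pixels per side), replacing the
  manual color-picker protocol while preserving its 3+6 counts and
  stratification. All sampling is reproducible from one integer seed via
  spawned child seeds per photograph.
* Annotations are per-photograph JSON; regions are 0-based half-open
  rectangles `[row0, col0, row1, col1]` or explicit pixel lists, required
  to be in-bounds and pairwise disjoint. Alpha channels are composited
  over white; deeper-than-8-bit images are rescaled to 8 bits.
* GPI_final may be negative and is never clipped.
* OLS fitting is delegated to statsmodels; standard errors use n−2
  degrees of freedom. Degenerate designs (all x equal) raise a
  singular-fit error rather than returning garbage.
* Simulation sizes in the test suite are chosen for statistical
  resolution: 5,000 replicates calibrate the slope-test type-I error
  (binomial SE ≈ 0.003 at α = 0.05), 100 seeded assays measure CI
  coverage and interval detection, 300 replicates suffice for the
  near-certain power check at five times the detectable slope difference.

## Known limitations

* One-grid-step localization of the linear-interval boundary is at the
  edge of what the default noise level supports: with per-photo noise
  0.002 the mean response one grid step past the breakpoint deviates from
  the line by well under one SD of a triplicate reading, so the detector
  overshoots by a second grid step in a minority of runs. The slope
  itself is essentially unaffected (CI coverage stays nominal).
* The %RSD convention (unweighted mean over back-predicted replicate
  concentrations) is sensitive to whether near-LoD samples carry
  replicates; report it together with the concentration range it covers.
* Only two-group comparisons are provided; multi-day or multi-condition
  designs are run as repeated pairwise calls without multiplicity
  correction.
* No weighted or robust regression and no nonlinear (e.g. four-parameter
  logistic) calibration: the method is defined by its linear interval.
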