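# Methods

## Problem and estimands

A third-trimester ultrasound (28+0 to 36+6 weeks) yields biparietal diameter
(BPD), abdominal circumference (AC) and femur length (FL). Hadlock Formula C
converts these to an estimated fetal weight (EFW), which a growth chart
converts to a gestational-age percentile; EFW ≥ 90th percentile is the
screen ("suspected LGA"). The outcome is LGA at birth: birth weight at or
above the sex-specific 90th percentile of a natality-style reference at the
completed delivery week. The estimands are the screen's sensitivity,
specificity, PPV, NPV and AUC per chart, the change in AUC when HbA1c is
added via logistic regression, and DeLong tests of paired AUC differences.

## Growth-chart engine

Charts are external reference files in one of three dialects: `mean_sd_log`
(GA → mean/SD of log10 EFW), `mean_sd_linear` (GA → median and SD in grams)
and `quantile_table` (GA → tabulated percentile values, optionally
stratified by race/ethnicity). Conventions, chosen where the source layout
left them open:

* Percentiles use exact decimal weeks with linear interpolation of chart
  parameters between GA knots (exact at knots); no extrapolation — GA
  outside chart coverage is a hard error, and every chart must cover
  28–37 weeks.
* `mean_sd` dialects: percentile = Φ((t(EFW) − mean)/sd)·100 with t = log10
  or identity. `quantile_table`: monotone linear interpolation across the
  percentile grid; EFW outside the tabulated spread reports the clamp
  bounds 0.5/99.5 rather than extrapolating.
* Thresholds are inclusive (≥ 90th percentile) for both the screen and the
  birth outcome.
* The birth-weight reference is indexed by completed (floored) week, the
  convention of published natality tables.
* A stratified chart queried with a stratum it does not contain is a hard
  error, never a pooled fallback; an optional `stratum_map` in the analysis
  config remaps cohort labels onto chart strata.

## Synthetic cohort generator

No subject-level data are public, so the generator is a first-class module
whose defaults encode the study population: n = 358; HbA1c 6.4 ± 1.2 %
(truncated to 3.5–20 %), 52/358 missing completely at random; scan GA
31.6 ± 1.5 weeks in the study window; delivery GA 37.2 ± 2.0 weeks (at
least one day after the scan, at most 42 weeks); BMI 35.4 ± 9.5 with 69 %
obesity; race/ethnicity 52.9/28.0/5.9/13.2 %; 33.6 % Type-1 diabetes;
36.9 % nulliparous; 51.2 % male infants (population sex ratio; the study
does not report it); target LGA prevalence 41 %.

The generative model is a probit latent-growth construction:

1. latent growth score `s = β·(HbA1c − 6.4) + ε + δ`, `ε ~ N(0,1)`;
   a missing HbA1c still contributes its drawn value to `s` (MCAR masking
   affects only the observed column);
2. `δ` is calibrated by Brent root-finding so the *expected* LGA fraction,
   `mean_i Φ(β·(A_i − 6.4) + δ − z_90)`, equals the target (unreachable
   targets — 0 or 1 — raise an error naming the parameter);
3. birth weight = reference median (sex, completed week) × 10^(σ_BW·s), so
   LGA at birth is exactly `s ≥ z_90`;
4. the observed EFW sits at z-score `s + N(0, σ_noise)` on the generating
   ("truth") EFW chart, evaluated with the same linear GA interpolation the
   percentile engine uses — with zero noise the truth-chart screen equals
   the birth outcome subject-for-subject, and noise degrades it smoothly;
5. biometry is back-solved: BPD and FL take deterministic GA-typical
   values and AC solves Hadlock C exactly (the formula is affine in AC at
   fixed BPD/FL with positive slope 0.0457 − 0.0034·FL, so the solution is
   closed-form and unique).

Key tunables: `hba1c_effect` (β, latent z per 1 % HbA1c; default 0.4, set
so HbA1c adds discriminative value of the order the study reports) and
`biometry_noise_sd` (σ_noise, ultrasound error on the chart z-scale;
default 0.9, calibrated once so the truth-chart screen reproduces the
study's observed accuracy of its best chart — sensitivity ≈ 76 %,
specificity ≈ 81 %, two-point AUC ≈ 0.79). Both are free parameters with no
directly published value.

Moment fidelity: truncated draws are *moment-matched* — the underlying
normal is solved (least squares on truncated moments) so the truncated
distribution has exactly the configured mean/SD. BMI uses a truncated skew
normal solved for three constraints simultaneously (mean 35.4, SD 9.5,
P(BMI ≥ 30) = 0.69), since no truncated normal satisfies all three; obesity
is then emergent from BMI ≥ 30. Draws are inverse-CDF transforms of
`numpy.random.default_rng(seed)` uniforms in a fixed order, so identical
(seed, config) gives byte-identical cohorts.

What the generator does **not** emulate: informative (non-MCAR) HbA1c
missingness, longitudinal growth trajectories, operator- or
habitus-dependent measurement error (noise is homoscedastic on the
z-scale), chart-specific EFW formula differences, or clinical outcomes
(Cesarean, shoulder dystocia, pre-eclampsia). Passing tests therefore
demonstrate correctness of the machinery under a clean data-generating
process, not performance on real cohorts.

The bundled demo chart suite is synthetic: an aligned log-scale chart, a
linear-dialect chart with the median shifted +4 % (screens ~34 % positive —
higher specificity, lower sensitivity), and a stratified quantile chart
whose per-stratum z-offsets (−0.65/+0.85/+0.45/+1.0) roughly cancel in
aggregate (similar screen-positive rate) while misaligning the threshold
within strata (lower AUC) — reproducing the qualitative pattern of the
three real references without transcribing any of their coefficients.

## Statistics

* **2×2 metrics** use exact Clopper–Pearson (beta-quantile) intervals; a
  zero denominator reports the metric as undefined, never 0. PPV/NPV are
  computed from the study 2×2 directly and are therefore prevalence-bound.
* **AUC** is the Mann–Whitney statistic with midrank ties (stated
  explicitly because binary flags produce massive ties); it equals the
  trapezoidal area under the empirical ROC, and for a binary flag equals
  (sensitivity + specificity)/2 — the "two-point ROC". Chart-alone AUCs
  feed the bare flag to the AUC (identical ranking to the one-predictor
  logistic model's fitted probabilities).
* **Logistic models** are fitted by Newton/IRLS (statsmodels) to relative
  tolerance 1e-10, max 100 iterations; complete separation and rank
  deficiency raise typed errors. Combined-model 2×2 metrics dichotomize
  fitted probabilities at 0.5 (the source does not state its cutoff; this
  is a reporting convenience, not a compared quantity).
* **DeLong comparison**: placement values per positive (fraction of
  negatives outranked, ties ½) and per negative; the variance of the AUC
  difference combines the 2×2 empirical covariance matrices of placements
  across the two markers, divided by the class sizes; two-sided normal
  p-values (the implementation matches R `pROC`'s `roc.test` to 7 digits
  on a fixture). Identical score vectors give z = 0, p = 1; zero variance
  with unequal AUCs is a typed degenerate-input error. AUC confidence
  intervals use the single-curve DeLong variance with a normal
  approximation, clipped to [0, 1]. No multiple-testing correction is
  applied across the pairwise tests; raw p-values are reported.
* **2×2 reconstruction** from published margins: every admissible integer
  true-positive count is scored by its worst deviation from the supplied
  rounded metrics; the minimizer must be unique and within 0.1 percentage
  points (one unit in the printed last digit, plus slack for rounding
  slips observed in published tables).

## Pipeline layout

`run_analysis` reproduces the study's reporting structure: the primary
accuracy table on the full cohort; the HbA1c-combined models on the
HbA1c-available subset (with flag-alone AUCs refit on the same subset for a
paired comparison); and chart-alone AUCs in three sensitivity subsets —
BMI ≥ 30 (inclusive), scan GA ≥ 32.0 weeks (the inclusive reading;
configurable via `scan_subset_min_weeks`), and HbA1c available. When a
subject carries multiple scans, the one closest to delivery is used. HbA1c
selection takes, per subject, the measurement with the greatest GA among
those strictly after 20 weeks; a measurement dated after delivery is an
error. Subsetting is a pure row filter, so results equal those from an
externally pre-filtered cohort.

## Problem sizes and numerical choices

Simulation-based tests use n = 10 000 for marginal recovery and
dose–response, n = 5 000 × 3 for the noise-degradation grid, n = 5 000 × 20
replicates for the HbA1c-gain check, n = 2 000 for noiseless limits, and
500 subjects × 2 000 resamples for the bootstrap cross-check of the DeLong
variance — sizes at which Monte-Carlo error is far below the assertion
margins while the full suite runs in well under a minute. Calibration
tolerances: δ root-finding 1e-12; moment-matching residuals < 1e-8
(truncated normal) and < 1e-6 (BMI grid, 6001-point inverse-CDF table).

## Known limitations

* The latent-growth model is single-factor: one score drives both the EFW
  percentile and the birth-weight percentile, with ultrasound error as the
  only wedge between screen and outcome. Real EFW–BW discordance also has
  systematic components (formula bias varying with habitus and GA).
* `hba1c_effect` and `biometry_noise_sd` are identified only through the
  calibrations described above, not from subject-level data.
* The AUC normal CI can degenerate to a point at AUC = 1 (zero DeLong
  variance); exact methods for that boundary are out of scope.
* Percentiles from `mean_sd` dialects lose strict monotonicity beyond
  |z| ≈ 8 where the normal CDF saturates in double precision — far outside
  any physiologic EFW.
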