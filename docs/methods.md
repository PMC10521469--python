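# Methods

This note documents the models implemented in `accelbalance`, the
numerical and design choices behind them, what the synthetic-data
generator does and does not emulate, and known limitations.

## Signal features

**ENMO.** Per sample, `max(0, (√(x²+y²+z²) − 1) · 1000)` milli-g.
Truncation of negative values happens per sample *before* epoch
averaging (the convention of the original wrist calibration work); 1-s
epochs are plain means, aligned to the recording start, with a trailing
partial epoch dropped.  ENMO is invariant to axis permutation and sign
flips and is exactly zero for any still posture.

**Sliding-window CV.** The two-regression models split non-sedentary
seconds by a coefficient of variation computed with a minimum-over-
windows rule: for second *i*, the CV (sample SD / mean × 100) of every
contiguous 10-s window containing *i* is evaluated and the smallest
kept.  Boundary-truncated windows participate if they retain ≥ 2
seconds.  Choices made here:

* *Window length* = 10 s, configurable.  The source calibrations defer
  the exact construction to earlier work; the enumeration-of-containing-
  windows reading implemented here is stated as this package's
  interpretation, not asserted as the original authors'.
* *Zero-mean windows* define CV = 0.  Such windows occur only when every
  second is zero ENMO, which is below every sedentary cut-point, so the
  convention cannot change a classification.
* Interior windows are computed vectorized over a strided view with
  numpy's two-pass variance; one-pass cumulative-sum variance was
  rejected because catastrophic cancellation left ~1e-8 relative errors
  that failed the enumeration oracle.

**Wrist linear-regression features.** Per 15-s window: sample SD of the
vector magnitude, and the mean inclination angle
`degrees(arcsin(clamp(a/|v|, −1, 1)))` of a reference axis (default the
first axis, forearm-aligned for wrist wear; configurable).  Samples with
zero vector magnitude contribute a zero angle and are logged.

## Energy-expenditure models and conversions

The five equations are implemented with their printed coefficients at
full precision and their published floors and ceilings (Hildebrand
[3, 70] ml/kg/min; two-regression [1.25, 20] METs; wrist linear [1, 20]
METs).  Decisions:

* The logarithm in the two-regression walking/running branches is the
  **natural log**.  The source does not state the base; base-10 yields
  physiologically impossible negative METs at ENMO = 1000 milli-g
  (≈ −2.7 for the left wrist), while ln gives 9.55 METs, consistent with
  the calibration's intent.
* The Hildebrand linear model's floor applies to the piecewise output;
  since the active branch already starts at 8.71 ml/kg/min just above
  the 44.8 milli-g cut-point, only the sedentary branch touches the
  floor, and the discontinuity at the cut-point is a property of the
  published form.
* Conversions: 1 MET = 3.5 ml O₂/kg/min; kcal at 4.862 kcal/L O₂ (Lusk
  table at RQ 0.85), scaled by period-start body weight.  Individualized
  food-quotient conversion is out of scope.
* Per-second (per-15-s for the window model) predictions are averaged
  over whole minutes before conversion; partial minutes are dropped.

## Wear screening and imputation

* **Non-wear**: a minute is non-wear iff it lies in a run of ≥ 90
  consecutive zero-activity minutes, where up to 2 total interrupting
  nonzero minutes are tolerated provided each interruption is ≤ 2 min
  and flanked by ≥ 30 zero minutes on both sides.  All parameters are
  configurable.  "Zero activity" for raw-derived input means minute
  ENMO < 1 milli-g — an adaptation of the count-based original, needed
  because sensor noise keeps worn-but-still minutes at a few milli-g
  while an unworn device sits at exactly zero.
* **Sleep** is an externally supplied minute mask; a fixed-window
  fallback (default 23:00–07:00) exists for simulations.  Detecting
  sleep from the signal itself is out of scope.
* Precedence non-wear > sleep.  Both are imputed identically, so the
  choice affects only awake-wear tallies.
* **Valid days**: ≥ 600 awake-wear minutes (≥ 10 h), inclusive;
  participants need ≥ 4 valid days.  First/last partial days face the
  same rule.  Both thresholds are configurable.
* **Imputation**: sleep and non-wear minutes on valid days get
  BMR / 1440 kcal/min, with BMR from the Schofield weight+height
  coefficient table (packaged as YAML keyed by sex × age band; height in
  metres; MJ converted at 239.006 kcal/MJ).  Alternative BMR equations
  can be swapped in through the same table format.

## Intake balance

ΔES uses energy densities of 1020 kcal/kg (fat-free mass) and 9500
kcal/kg (fat mass), exposed read-only in `intake_balance`.  The
denominator is generalized from the canonical 14 days to the actual
(possibly fractional) elapsed days between scans, since real periods
vary by a day or so.  EI = mean EE over valid days + ΔES, exactly.

## Validity statistics

Per-occasion metrics are bias (predicted − criterion), absolute error,
and percentage error (|bias|/criterion × 100).  Mean values are the
fixed intercepts of intercept-only linear mixed models with a random
participant intercept, fitted by REML (statsmodels `MixedLM`, a
conjugate-gradient pass refined by tight-tolerance BFGS; degenerate or
non-convergent designs fall back to the closed-form one-way
method-of-moments estimator, which coincides with REML on balanced
interior designs).  Intercept p-values use the large-sample normal
approximation on mean/SE — no specific degrees-of-freedom correction is
imposed, and SE and n are reported so other conventions can be
recomputed.  The Benjamini–Hochberg FDR step-up is applied across the
full family of metric × method tests in a run.

Repeated-measures Bland–Altman limits of agreement are
`mean bias ± 1.96 · SD` with SD the **total** random-effect SD
√(between² + residual²): limits are meant to bound individual occasions,
and the between-participant SD alone would understate the spread.  The
systematic-error model regresses bias on the criterion (fixed slope,
random participant intercept); marginal R² is the fixed-effect
fitted-value variance over total variance and conditional R² adds the
between-participant variance — the standard variance-partition
formulas.  A constant criterion leaves the slope undefined (returned as
NaN with a warning).

## Synthetic data

The generator emulates the study design the pipeline targets: multi-day
minute schedules with ~8.6 h/day sleep, occasional ≥ 90-min non-wear
blocks (averaging a few tenths of an hour per day), and
walking/running/intermittent bouts on a sedentary background; cohort
defaults (weight 73.7 kg, criterion EI centred on 2382 kcal/day) mirror
the published cohort summaries but are all configurable.

Traces are rendered as gravity plus per-axis Gaussian noise (sleep
σ = 0.010 g, sedentary 0.015 g), with locomotion as a 2-Hz sinusoid on
the x axis whose amplitude is calibrated by a root solve on the
closed-form phase-average ENMO (walk → 200 milli-g, run → 700,
comfortably across the 44.8/45.6/60.2 cut-points with low CV);
intermittent activity alternates second-level intensity (80/470 milli-g)
to force CV above the 19.4/21.2 % cut-points; non-wear is an exactly
still device.  This is deliberately *not* biomechanically realistic
gait: it exercises every branch of the equations and the CV classifier
with stable margins, which is what the tests need.  Consequently,
passing tests demonstrate correctness of the implementation and
internal consistency of the pipeline — not the field accuracy of the
prediction equations on real human movement, which only criterion
studies can establish.

Ground truth assigns each state a METs value (sleep/non-wear 1.0,
sedentary 1.3, walk 3.5, run 8.0, intermittent 4.0) and counts sleep and
non-wear minutes at the basal rate, the same accounting the pipeline
applies, so a pipeline run with truth substituted for the EE model
conserves energy exactly.  Body-composition pairs come from inverting
the storage equation at a target ΔES with a chosen fat-free fraction;
the round trip is exact to 1e-9 relative.  All generators are
deterministic given (configuration, seed).

## Problem sizes and numerical checks

The test suite runs the Monte-Carlo experiments at the sizes the checks
were designed for: validity-cohort recovery uses 200 participants × 2
occasions, averaged over 5 replicate cohorts to stabilise the slope and
coverage estimates (a single cohort leaves the Bland–Altman slope with a
sampling SD of ≈ 0.03, too noisy for a ±0.05 check); the mixed-model
closed-form comparison uses 100 random balanced designs generated with a
strong between-participant component so the REML solution is interior
(the closed form and REML agree only off the variance boundary);
non-wear recovery uses 20 simulated days.  CLI and end-to-end smoke
paths simulate 1–4 days at 20–30 Hz, rendered day-by-day to keep memory
flat.  Raw CSV timestamps are serialized at millisecond precision, so
the reader's sample-spacing validation allows a 1.5 ms quantization
floor on top of its ±1 % tolerance.

## Limitations

* Device binary formats (.gt3x/.agd) are not parsed; input is a CSV
  dialect.  No auto-calibration or band-pass filtering is applied.
* The neural-network and random-forest EE models from the same
  literature are not implemented (their trained weights are not
  published in usable form).
* Sleep detection is not implemented; sleep must be supplied or
  approximated by the fixed window.
* The criterion EE itself (doubly-labeled-water isotope kinetics) and
  DXA scanning are outside the package; they enter only as data.
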