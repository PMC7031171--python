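# Methods

This note documents the models, numerical choices and known limitations
of the `semgfatigue` pipeline, in the order data flows through it.

## Signal model of the synthetic generator

Real surface EMG is a stochastic interference signal whose power
spectrum compresses toward lower frequencies as muscle-fiber conduction
velocity slows with fatigue.  The generator does not simulate motor
units; it produces Gaussian noise whose *spectral median is known by
construction*.  Independent white-noise frames (512 samples, 50%
overlap, square-root-Hann windows so the overlap-add output has
stationary variance) are band-limited in the frequency domain to a flat
band of width `bandwidth_hz` (default 50 Hz) centred on the programmed
trajectory

    MF(t) = onset_mf · (1 + normalized_slope/100 · t),   t from contraction onset.

Band edges get fractional-bin amplitude weighting so the power median of
the band equals its centre rather than the nearest bin edge.  Because a
flat band's median is its midpoint, the analysis pipeline recovers the
programmed trajectory up to estimator noise.  Defaults emulate the study
conditions: onsets ≈117/101/85 Hz at L5/L2/L1, normalised slopes around
−0.2 %/s (young) and −0.12 %/s (old), signal RMS 150 µV with a 0.75 µV
noise floor, 2000 Hz sampling.  The accelerometer model is
z = sin(θ(t)) g with additive Gaussian noise (SD 0.01 g) and optional
8-bit quantisation over ±1.5 g (off by default).

What the generator does *not* emulate: amplitude nonstationarity
(RMS growth with fatigue), heart-beat and motion artifacts with
realistic morphology, nonlinear MF trajectories, inter-electrode
crosstalk, and spectral shapes other than a flat band.  Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every property of clinical recordings.

## Preprocessing

The first 3 s of the task are skipped and the analysis covers 3–30 s
(27 s).  Filtering is a 4th-order Butterworth band-pass (20–500 Hz)
applied forward–backward (zero phase, effective 8th order); zero-phase
filtering preserves epoch timing at the cost of non-causality, which is
irrelevant offline.  Recordings shorter than 30 s are rejected by
default (`allow_short` analyses the available tail with the same trim).

No artifact criterion is standard for this task, so screening uses a
conservative, reproducible two-part rule on non-overlapping 500-ms
epochs of the trimmed *raw* signal (clipping plateaus would be flattened
by the high-pass): an epoch is excluded if any sample reaches 99% of the
ADC full scale (default ±11 mV) or if its RMS exceeds 5× the median
epoch RMS.  Excluded epochs propagate as gaps in the MF series; a
recording with more than half of its epochs excluded is unusable.
Powerline notching and ECG subtraction are deliberately out of scope.

## Median-frequency series

Each epoch (Blackman window, 500 ms, 50% overlap, mean removed, one-sided
periodogram restricted to the 20–500 Hz band) yields the frequency at
which cumulative band power reaches half the total, with linear
interpolation inside the crossing bin — so a flat band returns exactly
its midpoint and discretisation bias is below the bin width.

The stated epoching produces MF estimates at 4 Hz (107 over 27 s), while
the analysis series is specified as 54 samples at 2 Hz.  These are
reconciled by averaging adjacent pairs of raw estimates onto a uniform
2 Hz grid (the final grid point holds the single trailing estimate).
Both outputs are available (`mf_output = "paired2hz" | "raw4hz"`).  A
2 Hz point is excluded only when *all* of its constituent raw epochs
overlap an artifact, so one isolated 500-ms artifact costs exactly one
grid point.

## Fatigue regression

Per electrode, ordinary least squares of MF on time over the
non-excluded points (≥4 required).  Time is referenced to the window
start, so the intercept is the onset MF at t = 3 s — the start of the
regression domain — not an extrapolation to t = 0.  Consequently a
channel programmed with onset 116.6 Hz and slope −0.19 %/s fits an
intercept ≈0.6 Hz lower and a normalised slope ≈0.6% steeper than the
programmed values; both offsets are far inside the recovery tolerances
and are properties of the convention, not errors.  The normalised slope
is the exact identity 100·slope/intercept.  Excluded points are omitted,
never interpolated.  Aggregates: "all" = arithmetic mean over the usable
electrodes (per-person six-electrode mean, not bilateral pooling first);
"most negative" = argmin of the normalised slope with ties broken in
canonical order (L5 left/right, L2 left/right, L1 left/right).  The
slope-vs-zero check is a one-sample t-test (the comparison is against a
constant) at the Bonferroni threshold p < 0.0025 (5 electrode aggregates
× 4 subgroups).

Estimator noise: with a 50-Hz-wide spectral band, one 2 Hz MF sample has
an SD of ≈3–4 Hz, which propagates to ≈0.06 %/s SD on a single
recording's normalised slope.  Recovery checks therefore bound the
*bias* (mean over ≥20 seeds per cell), which is the quantity the
generator contract fixes; per-recording scatter is irreducible at the
stated epoching.

## Imbalance

Raw right/left MF ratios are formed per level on jointly valid grid
points (an excluded point on either side drops the pair).  The
symmetric transform is the percent difference

    R(r) = (r − 1)·100        for r ≥ 1
    R(r) = −(1/r − 1)·100     for r < 1,

which satisfies R(1) = 0, antisymmetry R(r) = −R(1/r) and monotonicity;
it is pluggable (`"log"` → 100·ln r is provided) since the exact
historical transform is not uniquely determined by those properties.
Averaging order is transform-then-time; for constant ratios both orders
agree, which tests exploit as a cross-check.  The algebra guarantees
uncompensated ≥ |compensated| and that a left/right swap negates every
signed quantity while preserving the uncompensated value.

## Kinematics

θ(t) = asin(z(t)) with z in g units (traces in m/s² are divided by
g = 9.80665).  Samples marginally outside ±1 g (|z| ≤ 1.02) are clamped
— 8-bit quantisation at ±1.5 g can overshoot — and a trace with more
than 1% of samples beyond that is rejected as out of range.  The onset
angle is the mean over the first second of the analysis window (3–4 s),
so it includes any drift accrued by then; the drift rate is the OLS
slope of angle on time over the whole window.  No smoothing is applied
by default so the noise-free round trip is exact.

## Reliability (G-theory)

Measurement model: y_pds = μ + p + d + s + pd + ps + ε with subject,
day and side random facets; ds and pds are absorbed by the residual.
For balanced complete tables the components come from the closed-form
expected-mean-squares (EMS) ANOVA solution; for balanced designs this
coincides with REML whenever the estimates are interior, and it is
orders of magnitude faster, which matters for replicate-based recovery
checks.  Unbalanced tables (the intended real-data case, where some
subjects miss a day) fall back to REML via a variance-components mixed
model, and a test pins the two estimators against each other on
balanced data.  Negative solutions are truncated at zero and flagged;
the pre-truncation estimates are kept (`raw_estimates`) because they are
the unbiased quantities to average across replicates — the day and side
components sit on only 2 and 1 degrees of freedom, so their
single-cohort estimates have ≈100% relative SD *regardless of the number
of subjects*, and truncation biases them upward.  For the same reason a
single cohort's D estimate scatters by ≈0.05; recovery checks compare
means over replicate cohorts.

Single-observation dependability (n_d = n_s = 1) is the default report:

    σ²_abs = σ²_d/n_d + σ²_s/n_s + σ²_pd/n_d + σ²_ps/n_s + σ²_ε/(n_d·n_s)
    D = σ²_p / (σ²_p + σ²_abs),     SEM = √σ²_abs.

Side is treated as an error facet (part of σ²_abs), matching the quoted
measurement model; treating side as part of the object of measurement
would require only a different D-study design (n_sides = 2).

## Group statistics

`outcome ~ C(age)*C(sex) + C(test_day) + (1|subject)` fitted by REML
(statsmodels MixedLM) on per-subject-per-day values (side/electrode
replicates averaged first).  Sum-to-zero contrasts make the Wald tests
Type-III-like.  Denominator df use a containment rule — between-subject
terms: n_subjects − n_cells; within terms: n_obs − n_subjects − df_term —
recorded in the result (`ddf_method`) so a Satterthwaite-style
approximation could be swapped in and compared; at the cohort sizes of
interest (≥10 subjects/cell) the two differ negligibly.  Main effects
carry Bonferroni family-of-5 adjusted p values (significance p ≤ 0.01);
EMM subgroup contrasts (age within sex, sex within age) are
Holm-adjusted.  Cohen's d for model contrasts divides the EMM difference
by the model-implied between-subject SD √(σ²_subject + σ²_residual);
plain two-sample calls use the classic pooled-SD d.

The power simulation takes explicit per-comparison effect sizes (the
original study's programmed values are not recoverable), simulates
subject-level two-group comparisons at unit SD, and returns the smallest
grid n reaching the target power on every comparison, inflated for the
expected attrition fraction.  The two-group t-test path is exact for the
design it simulates and reproduces the closed-form
n = 2(z_{1−α/2}+z_{1−β})²/d² within a grid step; cohorts with the full
mixed-model chain are used for the calibration and detection checks in
the test suite instead, where the model, not the t-test, is under test.

## Problem sizes in tests and the acceptance script

Recovery and calibration checks use fixed seeds and the following sizes,
chosen as the smallest that leave comfortable Monte-Carlo margins
relative to their tolerances: 20 seeds per (onset, slope) grid cell;
1000 random cohorts for the imbalance algebra; 200 replicate cohorts of
500 subjects for variance-component recovery; 500–1000 null cohorts
(12 subjects/cell) for type-I calibration; 150–200 cohorts
(50 subjects/cell) for the d = 0.56 detection-power check.

## Known limitations

* The MF estimator is a single-taper Blackman periodogram; multitaper or
  AR alternatives are out of scope.
* Only linear MF trajectories are fitted; piecewise or exponential
  fatigue models are not provided.
* The group model uses a random intercept only (as specified by the
  design it mirrors); random slopes over days are not supported.
* EMS/REML equivalence holds for balanced designs with interior
  estimates; heavily unbalanced designs rely on MixedLM convergence.
* The CLI stages exchange tidy CSVs; no vendor acquisition formats are
  read.
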