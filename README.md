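# semgfatigue

Analysis of back-extensor muscle fatigue from surface electromyography
(SEMG), for researchers studying neuromuscular aging, chronic low back
pain and test-retest reliability of myoelectric fatigue markers.

During a sustained high-load back extension, the power spectrum of the
surface EMG compresses toward lower frequencies as the muscle fatigues.
This package implements the median-frequency (MF) fatigue method for
six-channel paravertebral recordings (lumbar levels L1, L2, L5, both
sides, 2000 Hz) with a lever-arm accelerometer (160 Hz) for mechanical
quality control, plus the statistical layers built on top of it:

* **Spectral stage** — 20–500 Hz zero-phase Butterworth band-pass,
  Blackman-windowed 500-ms epochs at 50% overlap, per-epoch spectral
  median; adjacent estimates averaged to a 54-sample, 2 Hz MF series over
  the 3–30 s analysis window.
* **Fatigue metrics** — per-electrode OLS fit MF(t) = IMF + b·t; the
  intercept IMF (onset MF, Hz) and the normalised slope
  100·b/IMF (%/s), aggregated as the six-electrode mean ("all") and the
  steepest electrode ("most negative").
* **Imbalance** — sample-by-sample right/left MF ratios per level,
  transformed to a symmetric percent difference R with R(1) = 0 and
  R(r) = −R(1/r); the "uncompensated" imbalance is the mean |segmental|
  across levels, the "compensated" one the signed mean.
* **Kinematics** — trunk-angle proxy θ = asin(acc_z/g); onset angle and
  drift rate (deg/s) as quality-control metrics.
* **Reliability (G-theory)** — crossed random-effects model
  y = μ + p + d + s + pd + ps + ε over subject/day/side facets;
  dependability coefficient D = σ²_p/(σ²_p + σ²_abs) and absolute
  SEM = √σ²_abs.
* **Group statistics** — linear mixed models
  `outcome ~ age * sex + test_day + (1|subject)` with Type-III F tests,
  Bonferroni family-of-5 adjustment, Holm-adjusted EMM post hocs,
  Cohen's d, and a Monte-Carlo power simulation for study sizing.
* **Synthetic data** — a generator that produces SEMG-like signals whose
  spectral median follows a programmed trajectory exactly in
  expectation, plus cohorts with known variance-component structure, so
  every stage is testable against ground truth.

## Worked example

```bash
python examples/01_fatigue_slopes.py
```

generates one 30-s recording with a programmed fatigue rate of
−0.19 %/s and prints:

```
electrode     onset MF (Hz)   slope (Hz/s)   slope (%/s)   r^2
L5_left           116.33       -0.2321       -0.200   0.13
L5_right          117.42       -0.2854       -0.243   0.17
L2_left            99.94       -0.2070       -0.207   0.11
L2_right          100.79       -0.2630       -0.261   0.16
L1_left            84.06       -0.1035       -0.123   0.04
L1_right           85.70       -0.1798       -0.210   0.10

all electrodes: mean onset 100.71 Hz, mean normalised slope -0.207 %/s
most negative electrode: L2_right (-0.261 %/s)
```

The onset MFs recover the programmed per-level values (≈117/101/85 Hz)
and the normalised slopes scatter around −0.19 %/s with the estimator
noise expected from 54 spectral medians; a more negative slope means
faster spectral compression, i.e. more myoelectric fatigue.  The other
examples cover imbalance (`02`), kinematics (`03`), reliability (`04`)
and group statistics / power (`05`).

A thin CLI mirrors the library for shell use:

```bash
semgfatigue simulate --seed 1 --out recs/
semgfatigue run --seed 1 --out results/ --recordings recs/
semgfatigue reliability results/side_metrics.csv --value-col slope_norm_side_mean --out rel.csv
```

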