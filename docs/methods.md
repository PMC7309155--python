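# Methods

`gaitrisk` implements a fall-risk prediction pipeline for elderly
nursing-home residents: gait-variability indices computed from a lumbar
IMU worn during a six-minute walking test, threshold-based clinical
classifiers built on the Timed Up and Go (TUG) test, and a frame-level
convolutional classifier on the raw signals. Because no sensor recordings
from the original study are publicly available, the package ships a
calibrated synthetic-cohort generator that reproduces the published group
statistics; every downstream stage is developed and tested against it.
This note records the models, the conventions, and the design decisions
that were genuinely open.

## Variability indices

For each of the six channels (accelerations a_ml, a_v, a_ap in m/s²;
angular velocities ω_ml, ω_v, ω_ap in °/s) over the *full* recording —
turnaround segments included — the pipeline computes:

* **SD** — the sample standard deviation (N−1 denominator), the magnitude
  of gait fluctuations in channel units.
* **D** — the box-counting dimension of the channel's graph, a
  dimensionless complexity index: D → 1 for smooth traces, D → 2 for
  maximally abrupt ones.

### Box-counting estimator

The graph of the linearly interpolated signal is covered with dyadic grids
of side ε = 2⁻ᵏ along the (min–max normalized) time axis, and
N(ε) — the number of grid boxes intersecting the graph — is regressed as
log N(ε) against log (1/ε); D is the least-squares slope. A box counts as
occupied if it contains a sample point or any part of the vertical span of
the interpolant inside its time column; within one column the extrema of a
piecewise-linear curve occur at sample points or column boundaries, so the
per-column count is exact and equals a brute-force O(N·boxes) enumeration.

Grid and fit-range defaults (all `BoxCountConfig` fields):

| parameter | default | rationale |
|---|---|---|
| `box_exponents` | k = 2…9 | spans coarse to near-sample scales for ~36 000-sample recordings |
| `fit_range` | k = 3…8 | trims the saturated coarse end and the sample-limited fine end |
| `aspect` | 8 | amplitude axis normalized to height 8 (time to width 1) |

The `aspect` parameter is the one genuinely non-standard choice. With a
square (1×1) normalization the one-box-per-occupied-column floor leaks
into the fit window at coarse scales and biases D downward for rough
signals: on exact fractional-Brownian paths of 36 000 samples the bias
reaches −0.10 at Hurst H = 0.2. Stretching the amplitude axis pushes that
floor out of the fit window while leaving the estimator scale-free
(min–max normalization first) and affine-invariant; at `aspect = 8` the
measured bias of the sweep H ∈ {0.2 … 0.8} stays within −0.07 ≤ bias ≤ 0.
Estimates are not clipped to [1, 2]; values outside by more than 0.05
trigger a warning. A constant signal is reported as D = 1.0 (a flat line)
with a warning.

**Finite-scale interpretation.** For six-minute recordings the fit window
(ε between ~1.4 s and ~45 s of the time axis) lies *above* the stride
period. A strongly periodic signal therefore looks band-filling at those
scales and measures D ≈ 2 regardless of its smoothness — D ≈ 1 for a pure
oscillation is recovered only when the grid resolves the period (short
recordings). The published index values of 1.7–1.8 are finite-scale
dimensions of noise-dominated signals, which is exactly how the estimator
treats them; this is also why the synthetic generator must put most signal
variance into the rough component (below).

## Synthetic gait cohorts

A participant's channel is synthesized as

    x = sqrt(1 − f) · carrier + sqrt(f) · roughness (+ bursts, ω_v only)

* **carrier** — three harmonics of the stride frequency (default 0.85 Hz,
  slow elderly gait; relative amplitudes 1 : 0.5 : 0.25, random phases).
* **roughness** — a standardized fractional Brownian path, synthesized by
  exact Davies–Harte circulant embedding; its Hurst exponent controls the
  measured D.
* **f** (`noise_fraction`) — the variance share of the rough component,
  default 0.95. At the estimator's fit scales the carrier is
  band-filling, so mixtures with f below ~0.9 cannot reach measured
  dimensions under ~1.8 and lose monotonicity in H; 0.95 keeps the
  H → D response monotone over H ∈ [0.05, 0.35] and spans D ≈ 1.71–1.86,
  bracketing every published channel median. The cost is a visually
  noise-dominated waveform — a deliberate trade of morphology for
  calibrated statistics.
* **bursts** — Gaussian-shaped peaks (width 1 s) in ω_v every 35 s,
  emulating the serial 180° turnarounds on a 25 m track walked at a
  typical nursing-home pace (~0.7 m/s); amplitude 60 °/s at the group's
  median ω_v SD. Bursts lower the measured D of ω_v (they dominate the
  min–max range), so the ω_v calibration includes them.

Each channel is rescaled post hoc so its sample SD *exactly* equals a
per-participant target drawn lognormally around the group median; gravity
(9.81 m/s²) is added to a_v. TUG times are drawn from the lognormal
distribution fitted to the group's published quartiles via
mu = ln(median), sigma = ln(q3/q1)/(2 z₀.₇₅); when the printed quartiles
are not symmetric in log space the median is matched exactly and the
quartile asymmetry is split evenly in log space. TUG and index draws are
independent by default (`tug_index_correlation` exposes a latent
correlation knob).

### Hurst calibration

The measured D of a carrier/fBm mixture has no closed form at finite
scale, so the generator inverts an empirical table: for a given signal
composition, D is estimated on `n_reps = 6` synthetic draws at each grid
H ∈ {0.05 … 0.35}; the mean table (with Monte-Carlo SEs) is cached per
composition and inverted by interpolation. Tables are checked for
monotonicity (a warning is raised if violated beyond 2 SE) and inverted
through their decreasing envelope. A median dimension target outside the
calibrated range raises `CalibrationError`; per-participant jitter around
a reachable median is clipped to the range instead. The calibration seed
is fixed, so cohorts are fully reproducible from their master seed
(per-participant seeds are spawned from it).

Because the estimator adds noise on top of the drawn target, the drawn
between-participant spread is deconvolved: draw SD =
sqrt(max(observed_spread² − estimator_sd², 0)), with the estimator SD read
off the calibration table at the group's median H. The calibrated range is
duration-dependent (shorter recordings shift the reachable D band down),
so the default targets assume ~360 s recordings.

### Group calibration

Default targets set *every* channel's SD and D median, and the TUG
quartiles, to the published faller/nonfaller values — including the
channels whose contrasts were not statistically significant (fallers'
dimensions are globally smaller). Between-participant spreads come from
the published interquartile ranges (lognormal for SD, normal for D).
Reproducing the whole table, rather than only the two significant
contrasts, keeps the cohort's joint feature distribution realistic; the
non-significant contrasts stay non-significant at n = 23/50 because their
effect sizes are small. Note that with these faithful spreads the
two significant contrasts have moderate power at the study's sample size
(≈0.7 for SDa_ap, ≈0.45 for Da_v at α = 0.05 two-sided) — consistent with
the borderline p-values the study itself reports — so a single 23/50
cohort does not always reach significance; distribution-level tests in
the suite use larger draws.

### What the generator does not emulate

Real trunk kinematics: joint-level gait mechanics, double support,
walking-aid use, pauses, within-walk fatigue drift, sensor saturation and
misalignment. TUG time is statistically independent of the walk signal by
default, whereas in reality both reflect the same mobility. Passing tests
therefore demonstrate that the *pipeline* recovers planted group
structure at the study's sample sizes — not that the published clinical
effect sizes are themselves reproducible from other populations.

## Risk classifiers

* **TUG** (`TugThresholdClassifier`) — ROC analysis of TUG times
  (higher = riskier, predicate strictly `time > cut`); the fitted
  threshold maximizes Youden's J = Se + Sp − 1, ties broken toward the
  lower (more sensitive) cut, and is reported as the midpoint between the
  adjacent distinct observed times so the classification is stable under
  infinitesimal perturbation. The ROC AUC equals the tie-corrected
  concordance probability exactly.
* **TUG+** (`TugPlusClassifier`) — three binary answers: TUG > t*,
  SDa_ap > s*, Da_v < d* (directions per the published group contrasts:
  fallers fluctuate more in anteroposterior acceleration and show lower
  vertical-acceleration complexity). The default `combine="or"` treats
  them as a three-question checklist (any positive answer flags risk); a
  `"sequential"` variant (risk only if TUG-positive *and* index-positive)
  is one option away. t* is held at the TUG Youden value; (s*, d*) are
  fitted by exhaustive accuracy search over observed-value midpoints,
  including on/off sentinels, in-sample — deliberately mirroring how such
  bedside rules are tuned on a full cohort (no cross-validation). Ties
  break toward higher sensitivity, then lower s*, then higher d*. Since
  the sentinels can switch both index questions off, the fitted TUG+ can
  never be less accurate in-sample than the TUG rule alone.
* **Logistic fusion** (`LogisticFusionClassifier`) — the same three
  features fused by maximum-likelihood logistic regression (risk =
  probability > 0.5); under perfect separation a ridge-penalized fit
  (alpha = 1e-4) is substituted with a warning. On synthetic cohorts the
  logistic fusion is typically *more* accurate in-sample than the
  checklist (gap ~0.1): the disjunctive rule can only add positives to
  the TUG answer, so it cannot repair TUG false positives, whereas the
  logistic reweights all three features. The two fusions should not be
  expected to coincide in general.

## Diagnostic statistics

Confusion-matrix statistics follow the standard definitions
(Se, Sp, PPV, NPV, Acc, LR⁺ = Se/(1−Sp), LR⁻ = (1−Se)/Sp). Ratios with an
empty margin are NaN (LR⁺ = +∞ at Sp = 1) and flagged by name in
`DiagnosticMetrics.undefined` rather than propagated silently. Display
rounding is 3 significant figures. Group differences use the two-sided
Mann–Whitney test (exact null for tie-free samples with min(n) ≤ 8,
normal approximation with tie correction otherwise). Paired classifiers
are compared with McNemar's test on the discordant counts b (A right,
B wrong) and c (A wrong, B right): continuity-corrected χ² =
(|b−c|−1)²/(b+c) when b + c ≥ 25, exact two-sided binomial otherwise;
both variants are selectable.

## Frame CNN

Recordings are cut into 20 s frames — overlapping by 10 s for training
only, non-overlapping for validation/test — standardized per channel with
statistics frozen on the training participants, and scored by a small 2-D
CNN (channels × time, one input map) in NumPy:

* conv stages (filters, kernel h×w, time stride, time pool):
  8 @ 3×7 stride 4; 16 @ 3×5 pool 4; 32 @ 2×5 pool 4,
* global average pooling over time, then dense 64 → 16 → 1 with sigmoid,
* class-weighted binary cross-entropy (positive weight = n₋/n₊ of the
  training frames), AdamW (lr 3e-3, weight decay 1e-4), batch 32, at most
  40 epochs with early stopping (patience 5 after a 15-epoch floor) on a
  participant-wise validation fold (15 % of training participants per
  class) with best-weights restoration.

Global average pooling instead of flattening is the decisive
regularization: gait is statistically stationary within a frame, so
features should be position-free, and the flattened head's ~60 k dense
parameters otherwise memorize the 57 training participants (training
frame accuracy ~1.0 with held-out participant accuracy near chance).
After training, the final pre-sigmoid bias is shifted so the midpoint of
the two classes' mean participant scores on the validation fold maps to
0.5 — the participant decision rule (mean frame score strictly > 0.5)
assumes centered scores, and class imbalance otherwise drifts the
operating point; only training-side data enters this calibration.

A participant's risk is the arithmetic mean of their frame scores,
strictly greater than 0.5 ⇒ at risk. The cohort experiment reserves a
balanced random test set (8 fallers + 8 nonfallers), trains on the
remaining 57 participants, and evaluates at participant level. Splits are
participant-wise throughout; no frame of a test participant influences
training, standardization, early stopping or bias calibration. Training
is exactly reproducible from the config seed (deterministic NumPy
primitives only).

Trained models persist to a directory (JSON config, NPZ weights and
standardization statistics) and can be reloaded to score new manifests.

Problem sizes: the study-layout experiment (73 participants × 360 s at
100 Hz; 1 995 training frames of 6 × 2000 samples) trains in roughly one
to two minutes per seed on one CPU core; the test suite runs the
experiment at exactly this size, five seeds for the calibrated cohort and
three for the zero-contrast control.

## Known limitations

* The box-counting D is a finite-scale quantity; its absolute value
  depends on the recording duration, sampling rate and the grid/aspect
  conventions above. Comparisons are meaningful within one convention.
* The Hurst calibration covers D ≈ 1.71–1.86 at 360 s (lower bands for
  shorter recordings); published per-channel interquartile ranges that
  extend below the floor are truncated there, slightly narrowing the
  generated spread for the most extreme channels.
* Synthetic cohorts calibrated to the published medians and IQRs carry
  only moderate class separability (participant-level Bayes accuracy
  ≈ 0.76 for the full 12-index profile); held-out accuracies of any
  classifier fluctuate strongly across 16-participant test draws.
* The CNN's accuracy is bounded by the information the generator plants
  (per-channel amplitude and roughness); it cannot exploit waveform
  morphology the generator does not model.
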