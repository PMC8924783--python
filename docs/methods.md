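# Methods

`bitewatch` detects eating from wrist-worn inertial sensors. The pipeline
runs: synthetic free-living data generation → cohort cleaning → sliding-window
segmentation and labeling → CNN ensemble training with on-the-fly
augmentation → window-level metrics → meal-level aggregation, call alarms and
false-positive accounting → optional per-individual fine-tuning. This note
records the model, its assumptions, the parameters that matter, and the
choices made where the design was genuinely open.

## The detection problem

A participant wears a watch on the eating-dominant wrist; accelerometer
(g) and gyroscope (rad/s) triples are recorded at 50 Hz, segmented into
files per participant-day, possibly spanning several recording *sessions*.
A diary supplies ground truth: `tag` marks any eating time, `tagTimely` tags
entered during eating, `tagRetro` tags recalled after the fact. The
classification unit is a 300-second window advanced by a 20-second step from
the first sample of the day:

* label **1** when strictly more than 150 s of in-window time is tagged
  mealtime;
* label **−1** (excluded from training *and* evaluation, retained for audit)
  when the window spans two sessions, overlaps any retrospectively tagged
  sample, or overlaps a meal shorter than 3 minutes;
* label **0** otherwise.

The −1 rules take precedence over the majority rule, so a retrospective
meal's windows are excluded rather than counted positive. Training sets are
balanced by oversampling positives with replacement until they match the
negatives (`N = #neg − #pos` duplicates); validation and test sets keep the
original imbalance.

## Synthetic data generator

The study cohort is private, so every stage is exercised on synthetic days
that reproduce the marginal structure the analysis depends on:

* recording days starting 7–9 AM and ending 7–9 PM (8–15 h modal duration),
  optionally broken into 2–4 sessions by 5–40-minute gaps;
* 1–7 meals/day with the mode in 1–4; log-normal durations
  (ln N(log 13, 0.6) minutes, clipped to 4–75), putting ≈76 % of meals under
  20 minutes; start times drawn from a three-component Gaussian mixture at
  breakfast/lunch/dinner (08:15, 12:30, 18:45, σ = 45 min);
* a **bite gesture**: a raised-cosine rotation pulse of 1–2.5 s, peak
  amplitude `gesture_amplitude` (default 2 rad/s) on a participant-specific
  unit axis with a correlated acceleration component (0.06 g per rad/s),
  repeating every 4–9 s during meals;
* **baseline motion**: band-limited Gaussian noise (Butterworth-filtered,
  ≈1.5 Hz cutoff, σ = 0.25 rad/s for gyro, σ/5 for acceleration around a
  −1 g gravity offset) plus Poisson arm-swing confuser bursts (5/h, 5–20 s,
  0.3–1.2 Hz, amplitude 0.6× the bite amplitude) so the task is not
  trivially separable;
* noncompliance artifacts: retrospective tagging (per-meal Bernoulli,
  default 0.1), watch-off segments (near-zero signal, default probability
  0.05/day), and injectable short days / all-retro days / meal-free days.

Per-participant jitter (amplitude ×U(0.75, 1.35), bite interval
×U(0.8, 1.3), random gesture axes) makes individuals distinguishable, which
is what gives personalization something to recover.

What the generator does **not** emulate: real bite-to-bite kinematic
variability, utensil-specific motion signatures, posture and gait context,
smoking-like confounders, or nondominant-hand wear. Passing tests therefore
demonstrate that the pipeline recovers structure it is designed for — not
field performance on real cohorts, whose published window-level AUC (~0.83)
is substantially below what the cleaner synthetic signal yields (>0.95).

## Cleaning rules

Exclusions are applied in order: (1) participants whose retrospective-meal
fraction exceeds 50 % across all their days (strict `>`; exactly half is
retained); (2) days totaling under 3 recorded hours summed over sessions;
(3) days with no meal events. Watch-off segments (5-minute rolling mean of
summed |accl|+|gyro| below 10⁻³) are detected and logged but never
auto-removed — observability without inventing an exclusion rule.

## Network and training

Ten blocks of (valid 1-D convolution, stride 1 → batch normalization → ReLU
→ max-pool), filters (8, 16, 16, 32, 32, 64, 64, 128, 128, 256), kernels
(11, 10, 10, 8, 9, 6, 7, 4, 5, 2), then a global max-pool over time and one
fully connected sigmoid unit (~0.24 M parameters at 3 input channels).
Weights are Glorot-uniform; the loss is binary cross-entropy under Adam.
The layer stack, backpropagation and the optimizer are implemented directly
on NumPy arrays (im2col convolutions), keeping CPU training at synthetic
scale inside seconds per epoch and inference a pure function of weights and
input.

Open details resolved as package choices:

* **Pooling plan** — pool size 2 after each block whenever the remaining
  length still supports the rest of the kernel cascade, else 1; global
  max-pool after block 10. This reduces the 15 000-sample default input to a
  single feature per filter and also accepts reduced-rate inputs (minimum
  63 samples). Overridable via `ModelSpec.pool_sizes`.
* **Activation/padding/batch size** — ReLU after batch norm, valid padding,
  batch size 64 (32 in the reduced-scale configuration).
* **Best-epoch callback** — "best performance on the validation set" is read
  as minimum validation loss by default; validation AUC is available via
  `TrainConfig.best_epoch_metric`.
* **Modality** — the gyroscope-only 3-channel model is the default, as the
  best-performing input; accelerometer and 6-channel variants are selectable.

Normalization is per window and per axis: centering (default) or z-score
with the population σ and a σ = 0 guard mapping constant (watch-off)
channels to zeros. Augmentation is training-only and per window, applied
before normalization: magnitude scaling by one shared U(0.8, 1.2) scalar,
and optionally a single random rotation (random orthonormal frame, angle
U(0, 2π), Rodrigues form) applied identically to both sensor triples, since
both share the physical reference frame.

The ensemble trains five members on five resampled train/validation subject
splits (3 test / 2 validation / 9 train by default, test fixed); the
ensemble score is the arithmetic mean of member scores. Personalization
deep-copies each member and continues training for 2 epochs on 60 % of the
target individual's days (20 % validation for the best-epoch callback, 20 %
held out as test); it requires ≥5 days so the split is non-degenerate.

## Metrics and aggregation

Window metrics: ROC AUC, AUPRC (baseline = positive prevalence),
class-proportion-weighted F1, positive-class precision/recall, and the
rebalanced weighted accuracy `(w·TP + TN)/(w·(TP+FN) + TN+FP)` with
`w = #neg/#pos` — the equation itself is a reconstruction from the cited
formula sources, flagged as such. Ranking metrics go through scikit-learn;
a brute-force pairwise oracle cross-checks AUC in the tests.

Model comparison uses paired resampling: per repeat, 1500 positives and
1500·R negatives (R = #neg/#pos, preserving the original imbalance) are
drawn, both models are scored on the same draw, and p is the fraction of
100 repeats in which the candidate fails to beat the reference, ties
counting half (identical models give p = 0.5 exactly). One-sided by
construction; a (x+1)/(n+1) continuity option exists.

Meal-level aggregation averages the scores of windows whose **midpoints**
fall inside each diary meal (≥3 minutes, non-retrospective) — the midpoint
rule lets meals shorter than one window length still own windows — and
compares them against an equal number of length-matched negative regions
sampled away from all meals with a 10-minute buffer at each end.

Alarms rescore the stream on a 10-second-stride window grid (inference on
the grid, not interpolation). A window is positive above a 0.3 score
cutoff; a *call* fires when strictly more than N = 3 positive windows occur
within a 5- or 10-minute horizon ("more than N" keeps the printed strict
inequality while N is sweepable). Per-meal recall asks for a call within
the first horizon after meal start. False positives per hour count distinct
false regions on meal-free time: call timestamps are covered greedily by
horizon-length intervals, so one sustained burst counts once and — because
lowering the cutoff only ever adds call points, and covering a superset
never needs fewer intervals — the rate is provably monotone nonincreasing
in the cutoff. The literal "(false − positive regions)/hours" bookkeeping
is available through `n_positive_regions`; on purely negative streams the
subtraction is vacuous.

## Reduced-scale configuration

The full-scale protocol (50 Hz, 280 k windows, ~40 k optimizer steps) does
not fit a desk run, so the end-to-end tests and `scripts/acceptance.py`
use a documented reduced configuration chosen up front:

* sampling rate 4 Hz (windows of 1200 samples); day structure, meal
  statistics and all labeling rules unchanged;
* per-member training subsets of ≤400 positives / ≤800 negatives (then
  oversampled to balance), validation capped at 600 windows, evaluation on
  a uniform 6000-window subsample of the held-out subjects — uniform
  subsampling leaves AUC and prevalence unbiased in expectation;
* Adam learning rate 1 × 10⁻³ with the same 5 epochs and batch size 32.
  The full-scale rate of 3 × 10⁻⁵ is calibrated to ~40 k steps; at the
  ~300 steps of the reduced run it would leave Glorot-scale weights
  essentially at initialization, so the reduced schedule compensates with a
  standard small-data rate. `TrainConfig` defaults keep the full-scale
  values.

## Numerical and degenerate-input choices

* All computation in float32 inside the network; scores in float64.
* σ = 0 (constant channel) → z-score outputs zeros, never NaN.
* Sigmoid evaluated in the numerically stable split form; BCE clipped at
  1 × 10⁻⁷.
* A day shorter than one window yields an empty window set, not an error;
  a one-sample diary run still produces a non-empty meal interval (1 ms).
* Session ids are taken as given on import; when ingesting raw timestamp
  streams a gap >1 s starts a new session.
* Every stochastic step (generation, splits, initialization, oversampling,
  augmentation, region sampling, resampling tests) consumes an explicit
  NumPy `Generator`; experiment-level seeds are derived from one master
  seed through `SeedSequence.spawn`, so a rerun with the same configuration
  reproduces all outputs.

## Known limitations

* The synthetic gesture model is deliberately simple; absolute metric
  levels on it exceed published field performance and should not be read as
  such.
* Batch-norm running statistics are estimated from a few hundred reduced-
  scale steps; very small training sets can leave them noisy.
* The exact pooling table, the validation metric of the original best-epoch
  callback, and whether reported p-values were one- or two-sided are not
  recoverable from the source material; the defaults above are declared
  reconstructions, each overridable in configuration.
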