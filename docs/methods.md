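# Methods

## Data model

A trial is one recording of one subject performing one ambulatory activity
(stair descent = 1, stair ascent = 2, level walk = 3, the figure-label
convention). Each time sample carries two 8-vectors of ordinal pressure
levels in {0, 1, 2, 3} ("no" / "slight" / "moderate" / "high" pressure),
sampled uniformly at a nominal 50 Hz. Sensor indices 1–2 are taken to sit
under the toes/forefoot and 7–8 under the heel; the hardware layout is only
depicted pictorially in this class of insoles, so the mapping is a declared
convention (`tawagait.trial.SENSOR_LAYOUT`) used only by the simulator —
every analysis stage is agnostic to it.

## Step detection

The reference step detector for this hardware is not publicly specified, so
the package uses a documented hysteresis substitute. Per foot, the summed
8-sensor level (range 0–24) opens a stance when it rises to
`on_threshold` (default 3) and closes it at the first sample at or below
`off_threshold` (default 1); runs shorter than `min_stance_samples`
(default 5 ≈ 0.1 s at 50 Hz) are discarded as contact artifacts. Hysteresis
makes the detector robust to single-sensor jitter on a small integer grid.
Stance intervals are half-open `[start, end)`; both feet are segmented
independently (double-support samples belong to both stances) and merged by
stance start, ties broken left-before-right for determinism.

## Feature family

With stance samples re-indexed per step to `k = 1..T`, the per-sensor
features are

* increasing weighting: `f1(i) = (1/T) Σ_{k=ΔT..T} P_i[k]·k`
* decreasing weighting: `f2(i) = (1/T) Σ_{k=ΔT..T} P_i[k]/k`
* time-independent:     `f3(i) = (1/T) Σ_{k=ΔT..T} P_i[k]`
* variation:            population standard deviation (divisor `T`).

Numerical and interpretation choices:

* **ΔT** is read as the first stance sample re-indexed to `k = 1` (default);
  this is the only reading consistent across all three accumulators and it
  keeps the inverse-time weight finite at the first sample, matching the
  continuous forms' `0+` lower limit. A warm-up offset larger than one
  sample is exposed as the `delta_t` keyword for sensitivity analyses.
* The **population divisor** (T, not T−1) keeps the variation feature
  defined for single-sample stances.
* `f1 ≥ f3 ≥ f2` elementwise for any stance (weights `k ≥ 1 ≥ 1/k`), with
  equality exactly when all pressure mass sits at the first sample; the
  test suite asserts these bounds and the strict monotonicity of `f1`/`f2`
  under shifting an impulse one sample later.
* An all-zero stance yields all-zero features (no special-casing).

Windows concatenate the per-step blocks of `k` consecutive steps of one
trial (stride 1, never across trials), preserving step order, rather than
pooling across steps: the observed gain of accuracy with window length
implies order/multiplicity information worth keeping. Feature dimension is
`32·k` with the variation feature, `24·k` without ("TAWA only" mode).
Features use the stance foot's 8 sensors only.

Normalisation is per-dimension z-scoring with mean/SD fitted **on the
training fold only**; zero-variance dimensions are centred but not scaled
(scale 1), so constant columns never divide by zero.

## Classifier

Scores are `f(z) = W⁽²⁾·relu(W⁽¹⁾z + b⁽¹⁾) + b⁽²⁾`, mean-centred over
classes. Centring is the orthogonal projection onto the sum-to-zero
constraint set, so `Σ_j f_j(z) = 0` holds exactly for every input and the
map stays differentiable; the gradient is backpropagated through the
projection. The objective is the summed multiclass hinge
`Σ_i Σ_{j≠y_i} (f_j(x_i) + 1/(ψ−1))₊` plus a Gaussian prior `(α/2) Σ w²`
on the weight matrices (biases are unpenalised).

Unspecified hyperparameters are fixed, documented defaults: margin constant
ψ = 2 (the canonical unit margin), α = 1e-3, hidden width 64, learning
rate 0.01 with 1/√epoch decay, 300 epochs, minibatch 32, seeded uniform
`±1/√fan_in` initialisation with zero biases. The SGD step averages the
hinge gradient over the minibatch (learning-rate scale independent of batch
size) and applies the prior as a clamped multiplicative decay
`w ← w·max(1 − ηα, 0)`, so extreme α shrinks weights to zero instead of
destabilising the update. Two independent models of the same architecture
are trained, one per task (3 activity classes; one class per subject).
`hidden_width=None` bypasses the hidden layer, exposing the plain convex
multiclass SVM used in convexity and oracle tests. Ties in the argmax
resolve to the lowest class label.

## Evaluation protocol

5-fold cross-validation assigned at the trial level, stratified by
(subject, activity) with seeded shuffling and round-robin dealing (balanced
within ±1 trial per stratum). Windows inherit their trial's fold, so no
window ever straddles train and test. Metrics are accuracy and
macro-averaged precision/recall/F1 (macro matches per-class-then-mean
reporting; whether a weighted average was ever intended is undocumented, so
the unweighted form is used); classes never predicted receive precision 0.
Pooled metrics concatenate the labels and predictions of all folds before
computing the contingency table. The metric computations are delegated to
scikit-learn; an independent hand-written contingency loop cross-checks
them in the tests.

## Synthetic cohorts: what they emulate, and what not

The generator reproduces the structure the method exploits:

* **Gait periodicity** — steps alternate feet; step k's stance starts at
  `k·(stance+swing)/2` samples, so opposite-foot stances overlap (double
  support) while same-foot stances never touch. Swing samples are zero up
  to noise.
* **Heel-to-toe rollover** — each sensor's continuous activation is a
  raised cosine (half-width 0.45 of the stance) whose center sweeps from
  the heel sensors (fraction 0.15) to the toe sensors (0.85).
* **Activity signature** — a per-activity spatial emphasis vector and a
  temporal skew γ that warps activation centers `c → c^(1/γ)`: γ > 1
  relocates pressure mass later in the stance (stair ascent, push-off
  dominated, γ = 1.35), γ < 1 earlier (stair descent, forefoot landing,
  γ = 0.75), level walk neutral (γ = 1). Center-warping was chosen over
  warping the evaluation time because a time warp changes traversal speed
  (the Jacobian) and can shift *aggregate* mass opposite to the intended
  direction; warping centers with fixed bump width moves mass monotonically
  and preserves the heel-to-toe order. Measured mass centers: descent
  0.526 < level 0.532 < ascent 0.572 of the stance.
* **Subject signature** — a log-normal per-sensor gain vector (log-SD 0.15)
  and a stance-duration multiplier (SD 0.08, clipped to [0.7, 1.3]), drawn
  once per subject, so identity lives in both amplitude and timing.
* **Quantization** — continuous force is cut at fixed thresholds
  (0.2, 0.5, 0.8) into the four hardware levels (level = count of
  thresholds strictly below the force).
* **Categorical noise** — per sample and sensor, probability `noise_level`
  of a ±1 level jitter clipped to range; categorical data gets categorical
  noise.

Default cohort size is 5 subjects × 3 activities × 6 trials × 12 steps at
50 Hz (0.45 s stances, 0.35 s swings) — a desk-scale cohort with the per-
trial step count of a short walking bout. The **mid-noise** condition is
`noise_level = 0.4`, calibrated so that one-step accuracy sits well below
ceiling and rises monotonically with window length (activity ≈ 90 % → 98 %,
pedestrian ≈ 56 % → 84 %), i.e. the regime where window length matters; at
low noise the synthetic task saturates at k = 1 and the trend is vacuous.

The generator does **not** model: continuous ground-reaction forces or
biomechanically validated load curves, gait variability within a trial
(every step of a trial shares its template), fatigue or speed drift,
sensor placement error, or inter-subject differences in rollover *pattern*
(only gain and timing differ). Passing tests therefore show that the
pipeline recovers structure of this kind when present — not that the
printed accuracies transfer to any real cohort.

## Determinism and problem sizes

Every stochastic component (cohort generation, fold shuffling, classifier
initialisation and batching) derives from explicit integer seeds; fixed
seeds reproduce byte-identical reports. The test suite and the acceptance
script run the full protocol on the default 90-trial cohorts (≈ 450–1 240
windows per configuration), sizes chosen to make cross-validated behaviour
measurable on a single CPU in minutes.

## Known limitations

* The step detector is a generic hysteresis detector, not a reimplementation
  of the insole vendor's method; on real data its thresholds would need
  calibration.
* The hinge objective is optimised by plain SGD with a fixed schedule; no
  early stopping or validation-based tuning is performed anywhere, which is
  deliberate (determinism, no leakage) but suboptimal for raw accuracy.
* Closed-set identification only: a subject outside the enrolled set is
  always mapped to some enrolled identity.
* Both-feet feature concatenation and warm-up offsets (`delta_t > 1`) are
  exposed but unexplored.
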