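# Methods

This note documents the models, conventions and numerical choices behind
`subtremor`, and what the synthetic test bed does and does not show.

## Kinematic model

Orientation samples are unit quaternions `q = q0 + q1 i + q2 j + q3 k`
(scalar-first in memory). The displacement signal is derived by rotating
a fixed reference point `P = (1, 0, 0)`: the rotated point is the vector
part of `q* P q` and the displacement at time `t` is the difference from
the rotated point at the first sample, so the first displacement sample
is exactly zero and the magnitude series is dimensionless.

**Conjugation order.** The conjugation is applied literally as `q* P q`.
This is the inverse of the common active convention `q P q*`; the two
differ only in rotation sense, which flips the displacement sign globally
and leaves magnitudes — and therefore band-limited power, STFT magnitudes
and class separability — unchanged. The rotation-matrix oracle in the
test suite pins this convention (`R(q)ᵀ P`).

**Joint angles.** Wrist angles come from the forearm→hand relative
quaternion `conj(q_forearm) ⊗ q_hand`, elbow angles from the
upperarm→forearm relative quaternion. Each is decomposed into intrinsic
Euler angles with a fixed anatomical mapping: wrist `Z–Y–X` with Z = WFE
and Y = WAA; elbow `Z–X–Y` with Z = EFE and X = EPS. Any fixed,
documented convention serves, because the simulator composes sensor
orientations from the same convention and the rating regression consumes
only mean-square power; the decomposition round-trips random relative
rotations to 1e-9.

**Normalization policy.** Quaternions are renormalized before rotation; a
deviation of the raw norm from 1 beyond 1e-3 warns, a zero norm is an
error.

## Tremor rating and the subclinical gate

The rating model is a linear regression of observational tremor rating
(average of six clinicians) on the log mean-square power of the four
joint angles, with published coefficients

    rating = 2.6496 + 0.3071 log θ_WFE + 0.0731 log θ_WAA
           + 0.1843 log θ_EPS + 0.0988 log θ_EFE

taken as given; this package does not refit them. A rating strictly
below 0.5 is subclinical. Two conventions are deliberately configurable
because the source leaves them open:

* **Log base** — default 10, the convention of regression-on-log-power
  models in this literature.
* **Angle units** — radians (θ_MS in rad²). A unit change shifts the
  rating by a constant through the log; the simulator calibrates against
  the same default, so the pipeline is self-consistent.

Joint-angle series are band-passed to 3–30 Hz before the mean square, so
the rating sees the same tremor band as the classifier features.

## Preprocessing

* **Gap repair.** Transmission loss is detected on the nominal 10 ms
  grid (a gap wherever consecutive timestamps differ by more than 1.5×
  the period). Each quaternion component is interpolated independently by
  shape-preserving piecewise cubic Hermite interpolation (PCHIP) onto the
  grid, then the quaternion is renormalized per sample. PCHIP reproduces
  retained samples exactly, reproduces linear segments exactly, and never
  overshoots monotone data. Interpolation happens at the raw-stream
  stage, before displacement conversion.
* **Band-pass.** 4th-order Butterworth, 3–30 Hz, applied forward and
  backward (zero phase) so STFT frame timing is not distorted. The
  filter is applied to scalar series: the displacement magnitude per
  sensor and each joint-angle series. Note that on a 13–14 s window the
  edge transients of the zero-phase filter leave a relative mean of up to
  ~1% of RMS in the output; DC rejection itself is better than 1e-3.
* **Standardization.** Every series is truncated to 13 s (1300 samples
  at 100 Hz), the minimum measurement duration of the motivating study;
  the window anchor is the first sample, configurable by offset.

The stage order is fixed: gap repair → displacement conversion →
band-pass → duration standardization.

## Features

Per sensor, the conditioned displacement magnitude is analyzed with a
128-sample periodic-Hann STFT hopped by 32 samples — bin spacing
100/128 = 0.78125 Hz (printing as 0.78) and frame step exactly 320 ms —
one-sided, magnitude only, no padding, so a 1300-sample series yields
⌊(1300−128)/32⌋+1 = 37 frames. Bins with centers in [3, 30] Hz are kept
(indices 4–38, 35 bins) and the three sensors are concatenated per frame:
37 × 105. Magnitudes are not log-compressed; scaling is handled by the
classifier's input-normalization layer. The scalar-magnitude choice (one
spectrogram per sensor, not per axis) matches the threefold feature
count; a per-axis variant would give ninefold.

## Sampling protocol

* **Holdout.** A fixed number of test recordings per class (10 in the
  clinical protocol) is drawn with a seed; with the study's class counts
  this reproduces the 82% (PD vs ET) and 87% (three-class)
  train/validation fractions. Subject grouping is on by default — up to
  two recordings may come from one subject, and no subject spans the
  train/test boundary.
* **Folds.** Per-class stratified 5-fold partition; every recording
  validates exactly once; per-fold class proportions are within one
  sample of global.
* **Augmentation.** A time slice of random length (uniform over 50–100%
  of frames, configurable) and random start is re-placed at a random
  offset in a zero sequence of the original length, varying the apparent
  onset. Minority classes in each training rotation are oversampled with
  such slices until classes balance (e.g. 58 PD + 20 ET → 116).
  Validation folds and the test set keep the original distribution and
  never contain augmented sequences.

## Classifier

Single LSTM layer with the standard gate equations (logistic input,
forget and output gates; tanh candidate; `C_t = f_t ⊙ C_{t−1} + I_t ⊙ C̄_t`).
The hidden output uses the universal `h_t = O_t ⊙ tanh(C_t)` — the gate
equations are not closed without it. The per-unit activations are summed
over time (sum pooling, implementing the printed activation-state sum
literally rather than last-step readout), then ReLU → 1–3 fully connected
layers → softmax over 2 or 3 classes.

Implementation choices:

* **Numpy with hand-written backpropagation.** The LSTM, the
  convolutional baseline, Adam and SGD are implemented directly on numpy
  arrays; training is deterministic for a fixed seed.
* **Input normalization** is a feature-wise standardizer whose mean/std
  are fit on the training set of each fold and frozen — batch
  normalization operating in inference mode. No gradient flows through
  the statistics; this keeps training simple and inference exactly
  reproducible.
* **Biases** are present and trainable (forget-gate bias initialized to
  1); equation-level unit tests zero them to check the bias-free printed
  forms.
* **Training**: categorical cross-entropy; Adam (default, lr 3e-3) or
  SGD; batch 32 (range 16–128 step 4); dropout after the aggregate and
  each hidden FC layer; L2 weight decay on weight matrices; early
  stopping when validation accuracy fails to improve for 10 epochs
  (default; max 80 epochs), restoring the best-validation weights.
  Defaults (hidden 50, one FC layer of 50, dropout 0.2, L2 1e-4) are
  modest capacities that train in seconds on one CPU.
* **Hyperparameter search**: seeded random sampling over the documented
  ranges — hidden units {10…300 step 10}, dropout log-uniform
  [1e-6, 1], L2 log-uniform [1e-5, 1], 1–3 FC layers of width {10…300
  step 10}, batch {16…128 step 4}, optimizer {SGD, Adam} — scored by
  mean 5-fold validation accuracy. The driver is sampler-agnostic; the
  search space and objective are the contract.
* **Baseline**: the comparison conv-LSTM — conv(30 filters, length 20,
  ReLU) → max-pool(2) → conv(30, length 10, ReLU) → max-pool(2) →
  time-distributed FC → LSTM — consumes the three preprocessed scalar
  displacement series (3 × 1300) by default and trains with the same
  loop.

## Evaluation

All scalar metrics derive from the confusion matrix (rows = true): TP/FN/
FP/TN give accuracy, sensitivity, precision, specificity, F1, FPR and
NPV; zero-denominator ratios are reported as NaN with an explicit flag.
Three-class results are collapsed one-vs-all per class. ROC sweeps the
softmax probability of the positive class; AUC is trapezoidal and
verified against the Mann–Whitney statistic to 1e-9. Published
worked-example tables occasionally disagree with their own confusion
counts (e.g. an F1 inconsistent with the harmonic-mean identity); this
package always reports the standard formulas.

## Synthetic data

The simulator emulates the measurement conditions rather than any real
patient: four joint-angle series are drawn from a class signal model — a
phase-continuous oscillator whose instantaneous frequency wanders inside
a class band, with slow amplitude modulation, optional harmonics, and
white + 1/f noise — composed into wrist/elbow relative rotations and then
into the three sensor orientation streams, so ground-truth kinematics are
known by construction and independent of the Euler convention.

Class models (defaults): PD 4–6 Hz with one 0.3-relative harmonic and
larger frequency jitter (low-amplitude PD tremor is less regular); ET
8–11 Hz; normal broadband 8–12 Hz at reduced amplitude with a heavier
noise floor. The defaults are narrowed inside the clinically reported
3–9 Hz (PD) and 4–14 Hz (ET) ranges so that the default preset is
reliably separable; the `overlapping` preset restores the full clinical
bands for a harder problem, and the `null` preset gives all classes one
model as a leakage guard. Amplitudes are rescaled by bisection until the
tremor rating lands in a per-recording target inside (0.1, 0.45), so
every simulated recording passes the subclinical gate. Transmission loss
removes a seeded 2% of samples (never the endpoints, so interpolation is
interior). Recordings last 14 s at 100 Hz; subjects contribute one or
two recordings.

**What passing tests show.** The synthetic classes are stationary,
noise-controlled and spectrally clean compared with clinical tremor;
success on the separable preset demonstrates that the pipeline is wired
correctly end to end (features carry class information, training
converges, no leakage), not that clinical accuracy would match. The
chance-level result on the `null` preset is the corresponding negative
control. Clinical phenomena not emulated: medication state, postural/
action conditions, asymmetry between limbs, sensor placement error, and
demographic covariates.

## Problem sizes and numerical notes

The shipped experiments use scales chosen to keep a full run in minutes
on one CPU: the surrogate experiment uses 60 training + 40 test
recordings per class; the leakage control 30 + 20. Bisection for the
subclinical calibration runs on the log-amplitude scale over [−8, 8]
with tolerance 0.005 rating units (the rating is exactly monotone in the
common scale because all regression coefficients are positive).
Degenerate inputs fail loudly: empty streams, zero-norm quaternions,
non-positive joint powers, too-short recordings, non-finite losses.
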