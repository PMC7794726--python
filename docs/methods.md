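# Methods

This note documents the models, the simulator, the numerical choices and
the limitations of the `resttremor` pipeline.

## Problem and pipeline

During a scripted clinic visit (~6 min of alternating exercises and
≥30 s rest blocks) a wrist-worn accelerometer records 50 Hz triaxial
acceleration. Rest tremor is only meaningful while the limb is at rest,
so assessment is hierarchical: a *context* classifier flags rest
windows, a *tremor* detector flags tremor windows, and the two surrogate
indicators are computed on windows flagged by both:

* amplitude = 75th percentile of La = 20·log10(a/a₀) with
  a = 3.5–7.5 Hz band RMS of the window's norm signal, a₀ = 1 μm/s²;
* constancy = 100 · (#rest∧tremor windows) / (#rest windows).

The percentile mimics a clinician rating the *largest* tremor excursion
seen during an exam while remaining robust to outliers; the constancy
denominator defaults to rest windows because rest tremor can only be
expressed at rest (a `denominator="total"` option reports the share of
the whole visit instead).

## Signal conditioning

* Band-pass: Butterworth 0.5–10 Hz, order 3, applied zero-phase
  (forward–backward). Zero-phase filtering has no group delay, which
  keeps window labels aligned with window content; band RMS is
  phase-invariant, so the assessment is unaffected by this choice.
* Windowing: 128 samples (2.56 s) with 50 % overlap; the trailing
  partial segment is dropped. Window labels use a strict >50 % majority
  per task; exact 64/64 ties and unknown-dominated windows are discarded
  (label −1) for that task.
* **Norm-then-filter.** The Euclidean norm a(i) = √(ax²+ay²+az²) is
  computed on the *raw* axes (gravity included) and the band-pass is
  then applied to that scalar channel. The order matters: gravity acts
  as a carrier, |g⃗ + s(t)·u⃗| ≈ g + s(t)(u⃗·ĝ), so the tremor appears in
  the norm at its physical frequency. Filtering the axes first would
  leave a zero-mean vector whose norm is a rectified magnitude with its
  energy at twice the tremor frequency — outside the analysis band.
  The per-axis filtered signal is still produced for the raw model
  input.
* Model inputs: `raw384` is the filtered 128×3 window mapped affinely
  from the sensor full scale (±2 g = ±19.6133 m/s²) to [0,1] — a fixed
  physical map, not per-window min–max, so normalization is
  deterministic, leakage-free across folds and preserves relative
  amplitude. `fft64` is the one-sided 128-point DFT magnitude of the
  filtered norm signal with 2/N scaling, DC dropped, bins 1..64 kept
  (0.39 Hz spacing) — the only reading that yields exactly 64 features
  from a 128-sample window.

## Band RMS and acceleration level

Band RMS is computed in the frequency domain: with X_k the DFT of the
mean-removed window, RMS² = Σ_band w_k |X_k/N|², w_k = 2 for interior
bins and 1 at Nyquist, band edges inclusive, no taper. With the full
band this is Parseval's identity and equals the time-domain RMS to
machine precision — the package's own correctness oracle. La is
undefined (flagged, not −∞) at zero RMS; doubling the RMS adds
20·log10 2 ≈ 6.0206 dB. The 3.5–7.5 Hz band sits well inside the
0.5–10 Hz passband, so filter droop is negligible.

## Network architectures and training

Three variants share one layer vocabulary (conv1d/ReLU, maxpool-2,
global average pooling, dense/ReLU, dropout, sigmoid head):

* single-output CNN (input 128×3): conv 128(k8) → pool → conv 96(k8) →
  GAP → dense 190 → sigmoid; 120,221 parameters, no dropout.
* multitask raw (input 128×3): conv 128 → pool → conv 128 → GAP, then
  two branches of dense 190 + dropout 0.2 + sigmoid (context, tremor);
  183,802 parameters.
* multitask FFT (input 64×1): as above with a 96-filter second conv;
  136,794 parameters. The 96-filter width is the one consistent with
  the published parameter table for this variant, and is adopted over
  the prose description of two 128-filter layers.

Parameter accounting is closed-form (conv: C·k·F+F; dense: in·u+u;
head: in+1; padding-independent) and is cross-checked in tests against
the built network's array sizes, including on randomized architectures.

Training uses Adam (β₁ 0.9, β₂ 0.999, ε 1e-7) with the per-variant
learning rates fixed at 0.0046 (context/FFT) and 0.0039 (multitask
raw), batch 64, binary cross-entropy per head summed unweighted, up to
200 epochs with early stopping (patience 10) and weight restoration
from the best monitored epoch. The monitor is a seeded 20 % validation
split of the training windows; monitoring the held-out test subject is
available behind `monitor="test"` for fidelity experiments but is not
the default, to keep the evaluation leakage-free. Multitask training
uses windows valid for *both* heads (the conservative intersection);
per-head masking (label −1) is supported for partially labeled data.
The whole stack is NumPy: weight init, shuffling and dropout draw from
one seeded generator, so identical seeds reproduce identical weights
bit for bit.

`conv1d` uses "same" padding (left-short/right-long split); parameter
counts do not depend on this. Single-output specs carry no dropout —
required for the 120,221-parameter arithmetic to describe the network
completely.

## Synthetic cohorts

Real patient recordings are not redistributable, so the simulator is a
first-class, tested module that defines the study conditions:

* visit script: six 30 s activity / 30 s rest cycles (360 s) by
  default; rest blocks never shorter than 30 s; blocks alternate.
* gravity: 9.80665 m/s² on a unit direction that is static at rest and
  drifts slowly (low-passed random walk) during activity.
* activity: 0.5–3 Hz band-limited noise at 3 m/s² RMS per axis — an
  order of magnitude above tremor level, making context classification
  non-trivial but learnable.
* tremor: injected only during rest (the pipeline assesses *resting*
  tremor), as an amplitude-modulated sinusoid (±20 % at 0.1 Hz) plus a
  second harmonic (ratio ∈ [0,1)), projected on a random unit direction
  re-drawn until its projection on gravity exceeds 0.3 so the norm
  channel carries it; per rest block a contiguous tremor-on run covers
  the profile's constancy fraction at a random offset, with 0.3 s
  cosine ramps.
* severity mapping: class 1 → 0.3 m/s², class 2 → 1.5 m/s² tremor-band
  RMS (±15 % per-subject jitter), ~14 dB apart so class separation
  tests are well-posed; class 0 ⇔ no tremor ⇔ zero constancy.
* sensor: white noise (σ = 0.05 m/s²) and hard clipping at ±19.6133
  m/s² (±2 g).
* cohort default: 18 subjects, 4 tremor-free (class mix {0:4, 1:7,
  2:7}), one seed governing every draw; identical seeds give
  byte-identical files.

**Amplitude calibration.** The target band RMS is enforced on the
quantity the assessment stage actually measures: per-window Parseval
band RMS of the 0.5–10 Hz-filtered norm channel, mean-square-combined
over the tremor-on samples of each rest block. Each block is rescaled
separately (three fixed-point passes) because the norm projects the
tremor vector onto the block's gravity direction, which changes between
blocks. Calibrating against a Butterworth 3.5–7.5 Hz refilter instead
would bias tremor frequencies near the band edges, where the IIR
roll-off and the rectangular bin sum disagree.

What the simulator does **not** model: biomechanically realistic
exercises, tremor leaking into movement blocks, re-emergent postural
tremor, gyroscope channels, sampling jitter or battery artifacts.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and self-consistent — not that the classifiers would reach the
same operating characteristics on clinical data, where class overlap is
far larger.

## Evaluation

* LOSO: one fold per subject; the subject-level partition guarantees
  that 50 %-overlapping windows never straddle train/test. Repeats run
  with distinct deterministic seeds derived from the base seed; with
  all seeds fixed, a repeated run reproduces the report exactly.
  Subjects whose held-out windows contain a single class for a task
  (tremor-free subjects for the tremor head) are excluded from that
  task's metrics. Fold metrics are computed per held-out subject and
  then averaged.
* Stratified 10-fold: seeded scikit-learn stratification on the joint
  context/tremor class of jointly-valid windows.
* Operating point: among midpoint thresholds between consecutive unique
  scores, the one minimising |sensitivity − specificity|, ties broken
  toward higher specificity then higher threshold (the equal-sens/spec
  criterion leaves the discrete-data rule open; this rule is fixed and
  oracle-tested against an exhaustive scan).
* AUC: midrank/trapezoidal (equals Mann–Whitney U/(n₁n₂)); Hanley
  SE = √[(A(1−A) + (n₁−1)(Q₁−A²) + (n₂−1)(Q₂−A²))/(n₁n₂)],
  Q₁ = A/(2−A), Q₂ = 2A²/(1+A); AUC differences compared by a normal
  z-test on independent SEs.
* Amplitude agreement: Shapiro–Wilk per severity group, Kruskal–Wallis
  across groups, Dunn's pairwise post-hoc (tie-corrected rank z-tests)
  with Bonferroni adjustment by default (Holm and unadjusted
  available). Dunn's test is implemented in-package. Note a power
  floor: with three groups of n = 8, even complete rank separation
  cannot push a Bonferroni-adjusted adjacent-pair p below 0.07; group
  sizes of ≥ 9–10 are needed for pairwise significance.
* Constancy agreement: Pearson r with two-sided p; constant vectors are
  rejected as undefined rather than returned as NaN.

## Problem sizes and tolerances

Tests and examples use scaled-down cohorts chosen as the package's
default desk-scale configuration: an 8-subject cohort with full 6-min
visits for oracle-prediction recovery (constancy within 2 percentage
points, amplitude within 1.5 dB — the residual amplitude offset is the
75th percentile riding the ±20 % AM envelope plus spectral leakage),
and a 6-subject cohort of 2-min visits for learned LOSO runs, where the
multitask FFT model trains in well under a minute per fold on one CPU
core. Larger cohorts (the 18-subject study layout, 6 LOSO repeats) run
with the same code paths via `simulate_cohort` / `run_loso` arguments
or the CLI.

Numerical edge cases are explicit throughout: zero-RMS windows carry an
undefined La and are skipped in the percentile; visits with no
rest windows report zero constancy; degenerate single-class training
labels, bands outside Nyquist, sub-window recordings, inconsistent
class mixes and constant correlation inputs all raise typed errors
rather than returning silently wrong numbers.
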