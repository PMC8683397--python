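# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the test suite demonstrates.

## Bivariate phase-rectified signal averaging and the FSI

BPRSA exposes coupling between two synchronously recorded series by
averaging target-signal windows aligned at events in a trigger signal.
Here the trigger is maternal heart rate (mHR) and the target fetal heart
rate (fHR), both interpolated linearly onto a common 900 Hz grid (the rate
of the interval's closing beat is placed at that beat's time, held constant
outside the beat support).  Anchors are trigger *decreases*:
`mean(m[i:i+T]) < mean(m[i-T:i])` with `T = anchor_T = 1` by default — the
single-sample decrease criterion of the original phase-rectified averaging
literature.  Indices within `L` of either edge are excluded so every anchor
admits a full `2L` window.

The averaged curve `X` has length `2L` with the anchor aligned at 0-based
index `L`.  The fetal stress index is

    FSI = 1/(S2-S1) * sum_{i=L+S1}^{L+S2} X(i)
        - 1/(S2-S1) * sum_{i=L-S2}^{L-S1} X(i)

implemented **literally**: inclusive bounds (each sum covers `S2-S1+1`
points) with normalization `1/(S2-S1)`.  A unit step at the anchor
therefore yields exactly `901/900` at the default geometry, not 1.  The
`mean_normalization` switch divides by `S2-S1+1` instead for the
conventional mean.  Defaults: `L = 9000`, `S1 = 1350`, `S2 = 2250` at
900 Hz, i.e. a 20 s window quantified between 1.5 s and 2.5 s on either
side of the anchor.  FSI is reported as after-mean minus before-mean of the
fetal curve; a fetus that decelerates with its mother gives a negative
value, and |FSI| grows with the coupling strength.

Numerics: on dense interpolated series nearly every sample on a descending
slope is an anchor (~10^6 anchors in a 40-min record).  Small anchor sets
are averaged by direct gathering (bit-exact, used by the oracle tests);
above ~2*10^7 gathered elements the computation switches to an FFT
cross-correlation of the target with the anchor indicator, identical up to
~1e-9 relative rounding.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
for everything downstream.

* **Beat times.** RR intervals follow a base interval (60/mean HR)
  modulated by two sinusoids (LF 0.095 Hz, HF 0.25 Hz; fractional
  amplitudes 0.03 / 0.08 maternal) plus white jitter (sd 0.01 of base RR).
  With all amplitudes zero the process is metronomic — the degenerate case
  used by exact tests.
* **Waveforms.** Each beat is a sum of five Gaussian kernels (P, Q, R, S,
  T) positioned and scaled as fractions of the local RR interval.  This is
  the standard analytic-control choice for ECG emulation; it makes R-peak
  positions exact ground truth.
* **Maternal-to-fetal coupling.** The fetal instantaneous heart rate is
  `base * (1 + HRV) + gain * drive(t - lag)` where `drive` is the negative
  part of the maternal HR deviation from a 60 s causal moving baseline (in
  bpm, always <= 0) and `lag` defaults to 0.5 s.  Gain 0 yields a fetal
  series statistically independent of the maternal one; |FSI| rank-orders
  the gain exactly across {0, 0.25, 0.5, 1.0, 2.0} on matched seeds.
* **Abdominal mixture.** `aECG = mECG + 0.3 * fECG + N(0, 0.02^2)` — the
  composite channel contains both hearts with the fetal contribution
  attenuated.
* **Quality model.** Each second is an artifact with probability 0.041
  (matching the reported ~4.1% discard rate of the emulated acquisition);
  artifact seconds draw SQI uniformly in [0, 0.5), clean seconds in
  [0.5, 1].  The waveform itself is left untouched: the SQI channel is the
  sole carrier of the quality information, as it is for the filtering rule.
* **Stress encoding.** A latent severity (N(+1, 0.6) stressed, N(-1, 0.6)
  control) drives every group difference: maternal mean HR (+5 bpm per
  severity unit), HF variability (reduced with severity), T-wave amplitude
  (flattened with severity), and the coupling gain (group mean 1.5 stressed
  / 0.4 control, plus 0.3 per severity unit).  Labels are monotone link
  functions of severity with Gaussian noise: `pss = round(12 +
  14*sigmoid(sev))` clipped to >= 19 (stressed) or <= 18 (control) so the
  diagnostic rule is consistent by construction; `pdq = max(0, round(10 +
  4*sev))`; `cortisol = exp(1.6 + 0.7*sev)` pg/mg.  These links are package
  choices, not clinical claims.
* **fsi_true** is computed by the BPRSA module on the noiseless beat-time
  series of each dyad — it therefore carries the estimation noise of a
  recording-length FSI, which is the realistic regression target.

What the generator does **not** emulate: fetal ECG extraction difficulty
(the fetal channel is emitted separately rather than deconvolved from the
mixture), electrode geometry, gestational-age morphology changes, fetal
sleep states, and any real covariate structure between labels.  Passing
tests therefore demonstrate that the pipeline recovers structure it is
designed to recover, not clinical performance.

## Preprocessing

Whole 1-s blocks with SQI strictly below 0.5 are discarded (equality is
kept — "lower than 0.5" read literally) and survivors concatenated; splice
counts are logged since segments may straddle a join.  Resampling to 256 Hz
is polyphase FIR (`scipy.signal.resample_poly`, anti-aliased,
deterministic).  Non-overlapping 10-s windows (2560 samples) are z-scored
per segment; constant segments are excluded.

## Self-supervised representation learning

Six transformations with desk-scale default parameters: Gaussian noise
sd 0.05 (of a unit-variance segment), scaling by a factor drawn from
{0.7, 1.3}, negation, temporal inversion, permutation of 20 equal pieces
(the last piece absorbs any remainder), and time-warping of 20 pieces with
ratio 1.05 (half stretched, half squeezed, resampled back to 2560
samples).  Each segment contributes one untouched row plus one row per
transformation; labels form one binary column per transformation with the
untouched rows all-zero.

The trunk is three convolutional blocks (two 'same'-padded 1-D
convolutions with leaky-ReLU 0.1, then max-pool 8), global max pooling,
and one parallel fully connected binary head per transformation with
dropout 0.5 at its input.  Default widths 8/16/64 and kernels 16/8/8:
wide enough that temporally asymmetric filters exist at initialization
(required for the time-inversion head), small enough that a cohort-scale
pretext run trains in minutes on one CPU.  Training uses Adam
(lr 0.001, batch 128).

Two numerical choices matter at this scale and are deliberate:

* **Class-balanced binary cross-entropy per head** (positive weight =
  number of heads).  The stacking construction makes every head 1:6
  imbalanced; unweighted BCE drives the shared bias to the base-rate logit
  and, within a short training budget, thresholded recognition never
  leaves the 6/7 floor.
* **Zero-initialized readout layers and a fixed post-pooling feature gain
  (default 5).**  With Adam the per-step weight movement is bounded by the
  learning rate, so logit movement per step is proportional to feature
  magnitude; zero-init removes large random initial logits and the gain
  makes the published learning rate effective at desk scale.  The gain is
  a fixed scale, not a learned parameter, and does not change what the
  network can represent.

Both trained weights and the loss trajectory are bit-reproducible from the
seed (pure numpy float32, explicitly passed generators).

## Affect recognition

The trunk is transferred frozen — enforced structurally: heads train on
precomputed trunk features, and the SHA-256 checksum of the trunk weights
is exposed to witness the freeze contract.  Heads are
Dense(features -> 64) + leaky-ReLU + dropout 0.5 + Dense(64 -> 1), with a
sigmoid output for classification (BCE) and a linear output for regression
(MAE on targets z-scored over the training data, predictions
inverse-transformed).  Subject-level scores are means of segment
predictions.

## Evaluation protocol

Each subject's segments are randomly divided into five near-equal parts;
fold k tests on the union of part k over subjects.  This *within-subject*
protocol places segments of every subject on both sides of the split — it
is the protocol behind the published evaluation style and is implemented
as stated; note that it estimates within-subject generalization, not
cohort generalization (a subject-wise split would be the honest estimate
for new subjects and is available via `contiguous`/custom splits).
Classification metrics use threshold 0.5; AUROC is the rank statistic
(normalized Mann-Whitney U), which equals trapezoidal ROC integration.
Fold-wise model comparisons use the exact two-sided Mann-Whitney U test
(the normal approximation is poor at n = 5) with Bonferroni-Holm control
across the stated comparison family (first-step threshold 0.05 / m).

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script, chosen as
the smallest sizes at which each phenomenon is unambiguous: coupling
recovery on 40-min dyads; pretext learnability on 200 training segments
for 2 epochs; the end-to-end experiment on 40 subjects x 10 min (about
2280 mECG segments), pretext 4 epochs, heads 150 epochs.  On that cohort
stress classification reaches held-out segment AUROC ~0.96-0.98 and FSI
regression R2 ~0.55 — close to the information ceiling of ~0.56 obtained
by predicting the (noisy, 10-min) FSI ground truth from the true coupling
gain.  The FSI-regression R2 varies by roughly +-0.1 across cohort
realizations because the FSI estimation noise itself varies.

## Known limitations

* The fetal channel is synthetic and separate; extraction from the
  composite abdominal signal is out of scope.
* FSI sign conventions in the literature differ; this package fixes
  FSI = after-mean minus before-mean of the fetal curve and documents the
  generator's sign (negative under positive coupling).
* The anchor criterion operates on densely interpolated heart rate, so
  anchor counts are large and the curve X is smooth; beat-domain anchor
  selection would give sparser anchors and noisier X.
* The within-subject protocol leaks subject identity by design (see
  above); reported numbers must be read as within-subject estimates.
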