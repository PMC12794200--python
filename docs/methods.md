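# Methods

`polardecode` implements continuous regression of the polar angle of
circular hand motion from multichannel EEG, together with the synthetic
study paradigm needed to exercise it end to end. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic data can and cannot establish.

## The decoding problem

A subject bimanually tracks a target moving clockwise at constant speed
around a circle (10 cm radius, one rotation in 6 s), over 20 sessions of
10 trials (1 s preparation, 6 s movement, 2 s rest). Hand position is
recorded by an overhead camera at an unstable 400–600 Hz; EEG by a
32-channel 10-10 montage at 256 Hz. The decoding target is the polar
angle θ of the hand about the circle centre, reported on [0, 2π) rather
than [−π, π) so that the wrap discontinuity sits at the movement's
start/end point instead of mid-rotation. The regression is trained with
a plain mean-squared-error loss on θ; the wrap is deliberately *not*
handled by a circular loss, so a small angular error across the wrap is
scored as an error near 2π. This inflates MSE/MAE at the trajectory
endpoints and is part of the protocol being replicated, not an
implementation accident.

## Synthetic paradigm

Real recordings for this task are not publicly deposited, so the
`synthetic` module generates surrogate subjects with the statistical
structure the analysis assumes. Per trial:

* **Kinematics.** The target angle is `θ(t) = (2π − ωt) mod 2π` with
  `ω = 2π / 6 s`. The hand follows through a first-order lag
  (default time constant 0.1 s) plus smooth motor noise (default
  0.3 cm SD per axis, ~20 ms correlation). Camera timestamps are drawn
  with per-sample intervals uniform on the reciprocal rate range;
  tracking losses (expected 1 per 20 trials) replace 1–3 samples with
  ~50 cm outliers.
* **EEG.** A spatially correlated 1/f background (unit-variance sources,
  amplitude-modulated by a slow envelope so their statistics are
  super-Gaussian like real EEG — also a precondition for ICA to be
  identifiable), plus: angle-locked `cos θ / sin θ` components projected
  on a bilateral sensorimotor topography (C3-weighted cosine,
  C4-weighted sine, default gain 5 µV, movement period only); 10 Hz and
  20 Hz oscillations over motor channels whose envelope drops by
  `erd_depth` (default 0.5) during movement; a slow central negativity
  ramping in over the second before movement onset (default 8 µV); brief
  frontal blink deflections (Poisson, 0.08 Hz, 150 µV — the
  physiological Fp range); and a 50 Hz line sinusoid. Spatial
  correlation uses a Gaussian kernel over 10-05 electrode distances
  (σ = 4 cm), which reproduces the strong short-range channel
  correlations of scalp EEG; purely random mixing does not.
* **Determinism.** Trial `(s, k)` of a subject seeds its generators from
  `SeedSequence([master, s, k])`, and each EEG component draws from its
  own spawned generator, so switching one component off leaves all
  others bit-identical — several oracle tests depend on this.

What the generator does *not* emulate: volume-conducted source dynamics
from a head model, non-stationary artifacts (movement, EMG, electrode
drift), inter-subject variability, or any nonlinear relation between
kinematics and cortical activity. Passing the recovery experiments
therefore shows the pipeline is correct and sensitive under its own
assumptions, not that the decoding accuracies transfer to human data.

## Kinematic labeling

Camera traces are linearly resampled to 1 kHz, repaired, centred on a
per-session least-squares (Kåsa) circle fit, converted to θ, epoched to
[−0.5 s, +6.5 s] around movement and decimated to 100 Hz. Outlier repair
flags samples deviating more than 3 cm from a rolling-median baseline
(31-sample kernel): single samples are replaced by the mean of their
neighbours, runs are bridged linearly, runs longer than 5 samples are
additionally flagged in the repair report. Angles are never filtered
directly — decimation low-passes `cos θ` and `sin θ` and recomposes the
angle, which avoids smearing the wrap.

The conversion itself is the quadrant-wise arctangent with the special
cases θ = 0 (x ≥ 0, y = 0), π/2 (x = 0, y > 0) and 3π/2 (x = 0, y < 0);
the measure-zero case (x < 0, y = 0) resolves through the π + arctan
branch to π. The origin is undefined and raises.

A geometry note: a 100-sample window's temporal midpoint falls between
samples 49 and 50, so for uniform rotation the circular mean of a
window's angles equals the interpolated mid-sample angle to numerical
precision, while the 50th-sample (index 49) label used for training
deviates from it by the half-sample rotation, 0.0052 rad. With motor
noise the gap grows; it is the practical analogue of the small
label-vs-window-mean difference expected under near-uniform motion.

## EEG cleaning chain

Fixed order: 50 Hz notch (zero-phase IIR, Q = 35) → 0.1–30 Hz zero-phase
FIR band-pass (Hamming windowed-sinc, 0.1 Hz transition, length capped
at half the data; applied twice to emulate forward–backward filtering) →
automated bad-channel detection (robust z of log-variance > 5, MAD floor
0.5 log-units; or max inter-channel |r| < 0.2) → spherical-spline
interpolation on the standard montage (refused above 25 % bad) → common
average reference → per-session ICA → epoching with baseline correction
(mean over [−1, 0) s before movement onset subtracted, epoch cut to
[−0.5, +6.5] s) → polyphase resampling 256→100 Hz (25/64), giving
32 × 700 epochs.

Note that the decoding target `cos θ(t)` is a movement-gated single
cycle at ~0.17 Hz, i.e. it sits just above the 0.1 Hz high-pass edge;
the gate's sub-0.1 Hz sidebands are necessarily removed by the
prescribed band-pass (~30 % of the component's total energy at these
settings). The chain invariant tested is therefore that all *other*
stages (notch, referencing, ICA) attenuate the surviving in-band content
by less than 10 %.

**ICA.** Unmixing is estimated by extended infomax (the EEGLAB-default
family) on a PCA-whitened, 1 Hz high-passed copy of the session, then
applied to the 0.1 Hz-filtered data, preserving the slow components that
carry the angle information. Ocular components are scored
deterministically as the geometric mean of three factors in [0, 1]:
prefrontal dominance (largest |loading| at Fp1/Fp2 over largest
anywhere), fraction of source power below 4 Hz, and source excess
kurtosis scaled to saturate at 10. The third factor is needed because a
1/f background also concentrates power below 4 Hz; only genuine blink
components (frontal, slow *and* transient) drive all three towards 1.
Components scoring ≥ 0.85 are removed in descending order, at most 3 per
session. On synthetic sessions blink components score ≈ 0.97 and all
others < 0.5, removal cuts ≥ 80 % of the blink variance at Fp1 while
preserving > 95 % of the angle-locked low-frequency content at C3.

## Dataset construction

Epochs are standardized per channel to zero mean and unit *population*
SD, with statistics pooled over all of a subject's epochs — matching a
standardize-before-split construction. This leaks a small amount of
test-set information into the scaling constants; a `train_only_stats`
mode computes statistics from non-test trials for methodologically
stricter runs. Windows are 1 s (100 samples) stepped by 0.05 s; a 7-s
epoch yields exactly 121 windows, each labeled with the angle at its
50th sample (zero-based index 49, configurable). After a seeded shuffle,
every k-th trial (k = count / 20, phase 0) enters the held-out test set
and the remaining trials are partitioned into 10 equal folds; assignment
is at trial level and a leakage guard asserts that no trial's windows
straddle the split.

## Decoders

Six architectures, all mapping a standardized 32 × 100 window to one
scalar through a linear output unit: ShallowConvNet (temporal conv, 40
filters → spatial filter over all electrodes → square → overlapping
average pool → log), DeepConvNet (temporal + spatial convs then three
conv/max-pool blocks, 25/50/100/200 filters), EEGNet (temporal conv with
8 filters and a half-rate kernel, depthwise spatial conv ×2, separable
conv, average pools 4 and 8), and their hybrids in which the flatten/
dense head is replaced by two stacked 64-unit LSTM layers reading the
preserved time axis of the final feature map (sequence lengths 11/2/3
for shallow/deep/EEGNet at 100-sample input), the second layer emitting
its final state. Batch normalization everywhere, dropout 0.2, ELU in
the deep and EEGNet families. Kernel and pool lengths are the canonical
ones expressed at 100 Hz and are clamped (with a log message) when an
input is too short; a hybrid whose time axis collapses below 2 steps is
rejected with advice to reduce pooling.

The layer library underneath (`polardecode.nn`) is a purpose-built numpy
implementation with hand-derived backpropagation, verified against
finite differences layer by layer and end to end. Performance-relevant
choices: channels-last feature maps; convolutions run as one BLAS GEMM
per bounded-size im2col chunk, with wide single-input-feature temporal
kernels routed through an exact FFT path (both paths agree to float32
precision and are cross-checked in tests); batch-norm uses fused affine
passes and einsum reductions. EEGNet's opening temporal-conv +
depthwise-spatial pair is evaluated in collapsed order (electrodes
summed first), which is algebraically identical because the temporal
kernel is electrode-independent and shrinks the dominant intermediate
map 32-fold; the batch-norm the canonical layout places between the two
stages is provably inert there — its per-feature affine is absorbed
exactly (up to the normalizer's eps) by the batch norm that follows the
pair, so the loss surface and all gradients are unchanged. Both the
fusion identity and the inertness are asserted numerically in the test
suite. Float32 throughout; float64 is switchable for gradient checking.
Weight init is Glorot uniform with a fixed seed; LSTM forget-gate bias
starts at 1.

## Training and evaluation

Per fold: train on the other nine folds, validate on the held-out fold,
early-stop when validation MSE fails to improve for 50 epochs (maximum
1000), restore the best-validation weights. Adam, learning rate 0.002,
no decay. Mini-batches are 9 whole trials = 1089 windows, reshuffled at
trial level each epoch; a smaller final batch is allowed when the trial
count does not divide by 9. Metrics on the pooled test windows: MSE,
MAE, Pearson CC (defined as 0, with a flag, for degenerate constant
predictions) and R². Cross-validation aggregates per-fold metrics as
mean ± SD and retains the across-fold mean predicted trace with a 95 %
t-interval.

The chance level repeats the identical procedure with training and
validation labels permuted at window level (one fresh permutation per
fold; test labels untouched; identity permutations rejected). Decoded
and chance metrics are compared fold-wise by one-way fixed-effects ANOVA
plus a paired sign-flip permutation test (exact enumeration up to 14
folds).

Early stopping treats an improvement smaller than `min_delta`
(default 10⁻⁴ rad²) as a plateau — without it, permuted-label models
creep downward indefinitely as their predictions contract toward the
label mean and never trigger the patience rule — while the best-so-far
weights are still tracked across sub-threshold improvements.

**Scaled study conditions.** The full protocol (200 trials × 10 folds ×
6 models, up to 1000 epochs) is out of desk range on CPU, so the
packaged experiments use reduced but structurally identical conditions,
chosen once: the angle-recovery experiment runs EEGNet+LSTM on 90
high-SNR trials (9 sessions × 10 trials; angle gain 30 µV over a 5 µV
background, reduced 2/1 µV oscillations; 9 test trials, 3 folds of 27,
≤ 25 epochs, patience 7); the chance-level calibration runs EEGNet on
24 default-SNR trials with 10 folds and ≤ 15 epochs. The pooled
recovery CC is computed on the across-fold mean prediction, the
analogue of the fold-averaged traces used for trial-level reporting.
Trial count is the decisive resource at this scale: with 16 training
trials per fold the decoders memorize trial-specific noise (test CC
≈ 0.5); with 54 they generalize (per-fold CC ≈ 0.80, pooled 0.83,
MSE ≈ 1.05 rad², MAE ≈ 0.55 rad on the ensemble). Remaining MSE/MAE is
dominated by occasional wrap flips near θ ≈ 0/2π, as expected under the
plain-MSE design.

## Neural signatures

MRCP: epochs (cut wider, −1.0 s, for these analyses) are band-passed to
0.1–4 Hz (zero-phase FIR; the transition width is relaxed to 0.5 Hz
because the kernel must fit a 7.5-s epoch), averaged across trials per
channel with a per-timepoint 95 % t-interval, no multiple-comparison
correction. ERSP: Morlet wavelets at 27 linear frequencies 4–30 Hz,
cycles = f/2 clipped to [3, 10], per-trial power averaged across trials
and converted to dB; baseline normalization is performed in the log
domain (mean dB over [−1, 0) s subtracted per frequency), which makes
the baseline-interval mean exactly 0 dB and keeps the whole-epoch
re-normalization invariant exact. Channel voltage summaries return the
across-trial mean voltage per channel at requested timepoints — the
numeric substrate of a topographic map sequence; spatial interpolation
and rendering are out of scope.

## Known limitations

* The decoders train on a single CPU in numpy; wall-clock budgets, not
  statistics, set the default experiment sizes above.
* The plain-MSE treatment of the wrap makes MSE/MAE near θ = 0/2π
  irreducibly large; circular losses are deliberately out of scope.
* The ocular scorer is a deterministic stand-in with the same contract
  as a trained classifier (threshold + cap), not a replacement for one.
* The synthetic generator's encoding model is linear and stationary;
  decoding accuracies on it quantify pipeline sensitivity only.
* ICA component quality on 54–90 s sessions is at the low end of common
  practice; the blink-removal figures above are for ~90 s sessions.
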