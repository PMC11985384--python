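# Methods

This note records the models, conventions and numerical choices behind
`somnoagree`, in the order data flows through the pipeline.

## Synthetic cohorts

**Hypnograms.** Sleep architecture is a first-order Markov chain over
{Wake, N1, N2, N3, REM} at 30-s epoch resolution. The default
transition matrix favours realistic dwell structure: long N2 runs (mean
run length 10 epochs), brief N1 visits, sticky Wake/N3/REM. This gives
the sequence-level model genuine temporal context to exploit. The
per-stage epoch fractions of long simulated nights converge on the
chain's stationary distribution (tested against an eigen-decomposition
oracle with the i.i.d. standard error inflated by
√((1+λ₂)/(1−λ₂)) for the chain's autocorrelation, λ₂ the
second-largest eigenvalue modulus).

**Biopotential signals.** The signal model is a sum of band-limited
Gaussian noise components (delta 0.5–4, theta 4–8, alpha 8–13, sigma
11–16, beta 16–35 Hz), each normalized to unit RMS and amplitude-
modulated per epoch by the square root of the stage's relative band
power — so measured band-power fractions match the recipe weights —
plus additive event templates: 1-s 13 Hz Hann-windowed spindle bursts
in N2, and in REM, biphasic deflections of opposite polarity (two
adjacent 0.4-s half-sine lobes) emulating the eye-movement signature of
a measurement electrode placed diagonally across the lateral
cross-section of the eye. A broadband 16–40 Hz component models muscle
tone, strongest in wake and weakest in REM. Units are µV throughout;
the default mixture RMS is 30 µV with 120 µV REM deflections. Two
recipes ship: a high-contrast forehead montage (the default study
condition) and a central-electrode-like "source montage" (stronger
spindles and delta, strongly attenuated eye deflections) used as the
transfer-learning source corpus.

The generator is deliberately minimal. It reproduces stage-conditioned
spectral content, event morphology, rejected-epoch artifacts and
clock-skewed pulse-rate pairs; it does **not** model K-complex
morphology, arousals, 1/f background structure, inter-patient spectral
variability beyond the seed, electrode pops, or cardiorespiratory
coupling. Passing tests on these cohorts therefore demonstrate that the
pipeline's machinery is correct and that the classifier can exploit the
signatures it is shown — not that clinical-grade accuracy would be
attained on real patients, where the same pipeline reports much lower
(published-level) agreement.

**Pulse-rate pairs.** The reference trace is baseline (65 bpm) plus a
stage-driven offset smoothed over ~1 min, a slow 0.01–0.05 Hz drift
(4 bpm RMS) and a respiratory-sinus-arrhythmia-like 0.15–0.35 Hz
component (2 bpm RMS), sampled at 1 s and clipped to [40, 120] bpm. The
fast component is what gives the alignment objective curvature at the
sub-second scale. The device trace is the same underlying process
resampled through t → stretch·t + shift plus independent Gaussian noise
(default 1 bpm); the reference plays the PSG-side ground-truth role and
carries no added noise.

**Rejected epochs** are injected as an i.i.d. Bernoulli relabelling to
Invalid (default fraction 0.03); the uncorrupted labels are retained
alongside for ground-truth scoring.

## Preprocessing

Bandpass 0.5–35 Hz, resample to 100 Hz, robust-normalize, then STFT.

- *Filter:* 8th-order Butterworth SOS applied forward-backward
  (`sosfiltfilt`). Zero phase matters because any group delay would
  skew epoch boundaries against the reference hypnogram. The order is
  chosen so the chain attenuates a 50 Hz interferer by ≥ 40 dB
  (a 4th-order design reaches only ~25 dB at 50/35 ≈ 1.43× the cutoff
  even applied twice), while leaving mid-passband tones (10 Hz) within
  5% of their amplitude.
- *Resampling:* polyphase at the exact rational ratio (256→100 =
  ×25/64), so there is no cumulative drift.
- *Normalization:* subtract the median, divide by the interquartile
  range, applied **last**, on the 100 Hz trace; a constant input (zero
  IQR) is rejected. Robust statistics keep large transient artifacts
  from dominating the scale of a whole night.
- *STFT:* per 30-s epoch, 2-s Hamming windows with 50% overlap, all
  windows fully inside the epoch: (30−2)/1+1 = 29 frames × 101 one-sided
  bins (transform length = window length = 200 samples). Frames never
  cross epoch boundaries so each epoch can be masked independently.
- *Log scaling:* `20·log10(max(|X|, 1e-8))`. The 1e-8 clip makes the
  floor value exactly −160 and keeps the transform finite; rejected
  epochs are set to this floor constant (the log-domain stand-in for
  zeroing their spectra) and flagged in the validity mask.

## Staging model

A hierarchical recurrent network in NumPy (float32, explicit
backpropagation, gradients verified against finite differences):

1. learned filter bank: linear projection of the 101 bins to 16
   subbands with tanh activation;
2. epoch-level bidirectional tanh RNN (16 units per direction) over the
   29 frames, pooled by additive attention (16-unit scorer) into one
   epoch embedding;
3. sequence-level bidirectional tanh RNN (16 units per direction) over
   windows of 20 consecutive epochs;
4. softmax over 6 classes.

Single-gate tanh cells are used instead of gated cells: at these widths
and sequence lengths they train in seconds on CPU and carry the same
sequential inductive bias; the evaluation here is property-based, not a
weight-level reproduction of any particular network. Inputs are
standardized by the training corpus mean/SD of valid-epoch log power and
clipped to ±7.5, so floor-valued (rejected) epochs present as a
distinctive saturated pattern.

The Invalid class is supervised like the physiological classes:
rejected epochs keep their place in each training sequence with
floor-valued spectra and the Invalid label, preserving the data's
sequential structure across measurement gaps. At prediction time the
contract is deterministic: masked epochs always emit Invalid; on valid
epochs the 6-class posterior is renormalized over the five stages, so
the output is always a 5-stage label (an unmasked epoch whose raw argmax
was Invalid thereby receives its runner-up stage). Ties break to the
lowest stage index (Wake < N1 < N2 < N3 < REM).

Training uses Adam (lr 3e-3), mean cross-entropy over non-overlapping
20-epoch sequences, batches of 32–64 sequences, 150–300 iterations
depending on the experiment; all randomness is seeded and single-run
deterministic. Transfer learning trains a base model on the source-
montage corpus and fine-tunes it (same architecture, carried-over input
standardization) on the target montage. Cross-validation is strictly
patient-wise: a balanced shuffled k-fold partition (sizes differ by at
most one), each patient predicted exactly once by a model whose
training folds exclude them — verified by a label-permutation leakage
test.

Experiment sizes: the cross-validation experiment uses 20 patients of
120 epochs (1 h) each with 10 folds; the transfer comparison uses a
6-patient source corpus, 4 training and 2 validation target patients,
3 seeds, measuring the first iteration (checked every 5) at which
pooled validation κ reaches 0.6. One-hour records keep a full study
run in the minutes range on a single core while leaving every
statistical mechanism — adequacy, invalid handling, fold balance —
fully exercised.

## Synchronization

The device→reference mapping is t_ref = stretch·t_dev + shift,
estimated by maximizing the normalized cross-correlation of the
linearly interpolated overlap of the two pulse-rate traces (minimum
overlap 10 min; flat or short traces are rejected). Search is
coarse-to-fine:

1. coarse: FFT cross-correlation on a 1-s grid for each of 9 stretch
   candidates spanning 0.998–1.002, correlation normalized by overlap
   length, shifts restricted to ±600 s;
2. refinement in a decoupled parametrization (μ, stretch), where μ is
   the reference-time image of the mean device time: a stretch
   perturbation rotates the warped trace about the overlap midpoint, so
   the objective is nearly separable in these coordinates — whereas in
   (shift, stretch) a stretch error δ biases the shift by δ·t̄ (hundreds
   of ms for t̄ ~ 10⁴ s). Two local grid rounds (μ to 0.01 s, stretch to
   2e-6) each end with a parabolic fit on the correlation peak.

On the default synthetic pairs this recovers shifts to a few tens of
milliseconds, comfortably inside the 100 ms requirement the acceptance
script checks.

## Hypnogram parameters

TRT is the sum of non-rejected epochs; TST the sum of sleep epochs; SE
= TST/TRT·100%. Sleep onset is the first epoch of the first run of at
least three consecutive sleep epochs (any sleep stage may compose the
run); SOL is wall-clock time from the recording start to that epoch,
and WASO the wake time after it. Conventions for cases the verbal
definitions leave open:

- an Invalid epoch inside a candidate run neither breaks nor extends it
  — rejection is a measurement gap, not physiology;
- TST counts *all* sleep epochs, including isolated pre-onset ones (it
  is defined from the sleep/wake partition alone, not from onset);
- when no qualifying run exists, SOL and WASO are undefined (`None`)
  and excluded from cohort aggregates;
- an all-Invalid hypnogram is rejected outright.

A device-vs-reference comparison is technically adequate when at least
30 minutes of epochs scored sleep by both sides (and valid in both) were
obtained; the threshold is inclusive.

## Agreement statistics

Confusion matrices count doubly-valid epochs only, reference on rows.
The 4-stage collapse sums N1 and N2 into Light Sleep and provably leaves
the Wake/N3/REM one-vs-rest metrics unchanged. Statistics are pooled
over epochs across patients, not averaged per patient: at ~8·10⁴ pooled
epochs the printed half-widths of a few thousandths are only consistent
with pooling. Confidence half-widths use the normal approximation
z·√(p(1−p)/n); for κ the coefficient itself is treated as the
proportion in this formula — an interpretation, recorded here, that
reproduces the conventional ±0.003-style half-widths reported alongside
pooled agreement tables. Pearson intervals use the Fisher z-transform
(undefined for n ≤ 3 pairs, flagged rather than extrapolated); limits
of agreement are bias ± 1.96·SD of the paired differences. No
multiple-testing correction is applied. Degenerate inputs are flagged
rather than coerced: a stage absent from the reference has undefined
sensitivity, a zero-variance margin has undefined correlation, chance
agreement of 1 has undefined κ.

The sample-size rule inverts the same κ-as-proportion half-width: the
smallest patient count whose pooled stage-epoch count brings the full
95% CI width of a postulated κ₀ under a target (0.1 by default). Under
κ₀ = 0.3 and 30 pooled N1 epochs per patient this gives 11 patients.
Published power calculations for comparable studies quote larger
numbers under additional unstated assumptions; this implementation
documents its own formula rather than guessing others'.

## Known limitations

- The synthetic cohorts are far more separable than clinical data; the
  classifier's near-perfect synthetic κ says nothing about clinical
  performance levels.
- The recurrent cells, widths, optimizer settings and attention
  parameterization are this package's own defaults, chosen for
  CPU-scale property testing.
- Synchronization models a single linear clock stretch; piecewise drift
  is out of scope.
- EDF output is a minimal single-channel writer (1-s records, 16-bit);
  reading goes through MNE.
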