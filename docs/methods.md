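# Methods

This note records the models, assumptions, numerical choices and known
limitations of the `silentspeech` package: a pipeline for recognizing
mouth motion and silently mouthed phonemes from a mixed EEG-EMG wearable
(one EEG channel near the left temple, one EMG channel at the jaw).

## Signal model and band decomposition

Raw channels are microvolt-scale time series sampled at 4 kHz by default
(the supported hardware also reports 4096 Hz; both work, and every test
and the fast profile use 500 Hz, which still satisfies Nyquist for the
highest band edge of 100 Hz).

Each channel is z-score normalized per channel before filtering (the
normalization improves the numerical conditioning of the filters and makes
band powers comparable across channels), then decomposed with zero-phase
Butterworth filters of order 4 (`sosfiltfilt`; forward-backward
application squares the magnitude response and cancels phase delay, which
keeps band traces time-aligned — a prerequisite for windowed covariance
between bands).

Canonical band edges, all overridable:

| band       | edges (Hz)      | channel |
|------------|-----------------|---------|
| alpha      | 8–12            | EEG     |
| beta       | 13–30           | EEG     |
| gamma      | 30–100          | EEG     |
| alpha+beta | 8–30            | EEG     |
| high gamma | 70–120          | EEG     |
| EMG low    | 0.5–25          | EMG     |
| EMG high   | 25–0.45·rate    | EMG     |

The loose "below 13 Hz" sense of *alpha* that appears in some of the
tongue-motion material maps onto the 8–12 Hz definition here; the edges
are config because the conventions conflict (below-13 vs 8–12; above-30 vs
30–100 vs 70–120). The EMG-high upper edge tracks the sampling rate so the
band stays inside Nyquist at any rate.

Filter edge effects: assertions in the test-suite exclude roughly three
periods of each band's low edge at the signal boundaries; returned data is
never trimmed.

## Moving-window covariance and correlation

Windowed second-moment features use a 500 ms window (2000 samples at
4 kHz) with a default stride of a quarter window (125 ms) for smooth
traces; the stride is config since no overlap convention is inherent to
the method. Covariance uses the n−1 denominator; correlation is Pearson
with per-window mean removal. Windows where either input is constant
yield the sentinel value 0 and are counted (and logged) rather than
failing the trace.

**Envelopes.** Band-limited signals at disjoint frequencies are nearly
orthogonal sample-by-sample, so raw-signal covariance between, say, alpha
and gamma is structurally near zero regardless of their co-activation.
The visible co-modulation between bands lives in their amplitude
envelopes. All cross-band second-moment features are therefore computed
on analytic-signal magnitudes (`scipy.signal.hilbert`) by default, with a
raw-signal mode available (`use_envelope=False`).

## Tongue-motion statistics

Each annotated movement event contributes one *pre* epoch (2 s
immediately before onset — the window in which peak activity concentrates)
and one *spike* epoch (the annotated event duration, 3 s in the standard
protocol). Pearson correlations between band envelopes are computed per
epoch for the pairs alpha–gamma, beta–gamma and alpha–beta, and the
pre-vs-spike contrast is tested with a classic one-way ANOVA
(F = between-group MS / within-group MS, p from the upper tail of
F(k−1, N−k)). With two phases of four repetitions each the reference
critical value is F(0.05; 1, 6) = 5.987. Degenerate cases are defined
explicitly: all values identical → F = 0, p = 1; zero within-group
variance with distinct means → F = ∞, p = 0. No multiple-testing
correction is applied across band pairs by default (a Bonferroni switch
exists).

## Synthetic data generator

No public recordings exist for this electrode montage, so the generator is
a first-class, tested component that emulates the reported statistical
structure rather than the physiology:

* **Carriers.** Every band component is Butterworth-filtered white noise
  rescaled to unit variance — band-limited but broadband within the band,
  so correlation/covariance features are non-degenerate (pure sinusoids
  would make windowed correlations trivial).
* **Baseline.** Outside events each band carries a configured variance;
  with amplitude modulation disabled the marginal amplitude distribution
  is Gaussian. The default configuration adds a slow (≤2 Hz) amplitude
  modulation shared across bands; this makes the marginal a Gaussian scale
  mixture (slightly heavy-tailed by construction) and gives the alpha and
  gamma envelopes their resting co-modulation.
* **Movement events.** Inside annotated events (3 s default) the gamma
  variance rises — the default spike:pre ratio is 4 — the EMG components
  are multiplied by a burst gain (default 3), and the gamma envelope
  switches from the shared to an independent modulation. The combination
  reproduces the two signatures the pipeline detects: a gamma power surge,
  and a decline of the alpha–gamma envelope correlation during movement.
  Event edges use 100 ms cosine ramps to avoid spectral splatter.
* **Phoneme samples.** Each sample is a 2 s two-channel recording whose
  EMG-low, EMG-high and gamma components follow a class-specific temporal
  envelope (Gaussian activation bumps on a normalized time axis), loosely
  articulatory: M — a single broad low-frequency closure; A — a sustained
  broad opening with stronger high-frequency EMG and gamma drive; D — a
  pair of short sharp bursts. Alpha and beta are class-independent resting
  rhythms. Intra-class variability comes from per-sample jitter of bump
  amplitude, timing and width; inter-subject variability from per-subject
  multiplicative band gains and a timing offset. The default dataset is 3
  classes × 2 subjects × 10 samples = 60 recordings.

The generator's class-contrast and jitter defaults were fixed once so that
the three classes are separable but overlap: the few-shot classifier with
augmentation reaches the reference accuracy level (≥95% pooled CV
accuracy) while the LSTM baseline lands materially lower, mirroring the
reference model ordering. Class identity is carried by **both** relative
band amplitudes and temporal envelope shape; the strong subject gain
offsets make raw amplitude partially unreliable, which is what gives the
translation-robust convolutional embedding its edge over the
last-step-state LSTM, and time-shift/crop augmentation its additional
margin.

Reproducibility: one global seed is fanned out through
`numpy.random.SeedSequence.spawn` to per-sample child seeds, so any subset
of the dataset regenerates bit-identically.

What the generator does *not* model: cortex-to-scalp propagation, sensor
contact artifacts, blinking, line noise, BLE packet loss or ADC
quantization — so a passing pipeline here demonstrates correctness of the
computation, not performance on real electrodes.

## Feature stacks for classification

Each phoneme sample yields eight traces: the four band signals (6-1 EMG
<25 Hz, 6-2 EMG >25 Hz, 6-3 alpha+beta, 6-4 gamma) and the four moving
correlations (7-1 = corr(6-1, 6-2), 7-2 = corr(6-3, 6-4), 7-3 =
corr(6-1, 6-3), 7-4 = corr(6-2, 6-4)) computed on envelopes.

For the neural networks the stack is assembled into an 8 × L matrix:
band traces enter as amplitude envelopes (resampling an oscillatory
carrier below its band frequency would alias it; the envelope carries the
activation information and survives resampling), all traces are linearly
resampled to a common length, and the four band rows are scaled by one
shared RMS so their *relative* amplitudes — part of the class signature —
are preserved while absolute scale is removed. Correlation rows are
already dimensionless in [−1, 1] and enter untouched.

## Classifiers

**Few-shot 1D CNN.** Nine blocks: six convolutional body blocks (1-D
convolution with stride 1 and same-padding, tanh activation, batch
normalization, max pooling k=2/s=2; block 1 additionally ends in adaptive
average pooling to a fixed length so the network is invariant to input
length) and a three-layer fully connected head ending in a length-64
embedding. Default kernels (7,7,5,5,3,3) and channels (8,16,32,64,64,64);
every block hyperparameter is exposed through `EmbeddingNetSpec` because
only the block structure, the adaptive-pool output and the embedding
length are fixed by the design.

Training uses a cosine-similarity contrastive loss

    L = mean over positive pairs (1 − cos(q, r))
      + mean over negative pairs max(0, cos(q, r) − margin),  margin = 0

where queries q are training samples and r the k = 3 reference embeddings
per class (references are excluded from the query set so no sample forms
a positive pair with itself; both query and reference embeddings receive
gradients). This is the simplest form with the required pull/push
behaviour; the margin is config. Prediction scores a query by its mean
(optionally max) cosine similarity to each class's reference embeddings;
ties break to the lowest class index. Reference sets are drawn at random
4 times, each short-trained (50 epochs by default), and the draw with the
smallest final training loss is kept.

**LSTM baseline.** Two layers: the first emits its full hidden sequence,
the second only its last step, followed by a fully connected layer to the
three class logits and softmax cross-entropy. Hidden size 64 per layer
(unstated in the source; a conventional choice), input resampled to a
fixed number of time steps with the 8 stack rows as per-step features.

**Optimization (both models).** Adam, learning rate 1e-4, batch size 16,
early stopping with patience 250 (training halts after that many epochs
without a new best validation loss), maximum 5000 epochs as a safety cap,
and the checkpoint from the best-validation-loss epoch is the returned
model. The validation fold of the running cross-validation iteration
drives early stopping.

**Backend.** Both networks run on a compact reverse-mode automatic
differentiation engine written in numpy inside the package
(`_autograd.py`): float64 throughout, standard Adam, fused batch-norm
backward, convolution as channels-last BLAS products. Every structured
operation is verified against central finite differences in the test
suite.

## Augmentation

Applied to training samples only, freshly randomized on every access;
validation and test samples pass through untouched. Whole-sample ops
(random slope, x-shift with edge replication, y-shift, amplitude scaling)
and windowed ops (hanging datapoint — a held value mimicking a brief
recording dropout; Gaussian smoothing; noise addition; downsampling with
re-interpolation so lengths stay stable) are shuffled into one random
order per access; random cropping keeps a contiguous 70–100% of the
sample (65–100%) and re-interpolates to the original length so batch
tensors stay rectangular. No magnitudes are inherent to the method, so
the defaults are mild and config-exposed: slope ≤10% of sample RMS per
duration, x-shift ≤8% of length, y-shift ≤10% of RMS, scale 0.8–1.25,
per-window probability 0.05, added-noise SD 10% of RMS. The x-shift and
crop magnitudes are sized against the generator's timing jitter so the
augmented model learns the timing invariance the task actually has.
Labels are never touched.

## Cross-validation protocol

10% of samples (six of sixty) are held out per iteration, ten iterations,
folds stratified by class (two samples per class per fold at n = 60). A
class exactly one sample short of `quota × iterations` has its first
sample (in shuffled order) reused in the first and last iteration; every
reuse is recorded in the plan. The whole cross-validation is repeated
three times with reshuffling; the best repetition is the headline number
(matching the reference convention) and the mean ± SD across repetitions
is reported alongside to discourage cherry-picking.

## Problem sizes (fast profile)

The package's full-size defaults (4 kHz sampling, 2000-sample windows,
lr 1e-4 with patience 250, full network widths) are impractical for a
routine desktop run of the three-model comparison, so the reproduction
script and the heavier tests use the documented fast profile:
500 Hz / 2 s samples, stacks resampled to 192 points, a narrower
embedding network (adaptive pool 64, channels 8,16,16,32,32,32), LSTM
hidden size 64 over 32 steps, learning rate 1e-3 with patience 40 (CNN)
or 30 (LSTM), epoch caps 150/100, and a 10-epoch reference-selection
budget. The profile is a scaled replica, not a different method: same
architecture family, same loss, same protocol. Full-size settings remain
the library defaults.

## Known limitations

* The synthetic generator defines the difficulty of the classification
  task; accuracies measured on it validate the pipeline, not the wearable.
* EDF files are read (via `mne`) but not written; the canonical on-disk
  format is CSV plus a JSON sidecar.
* The few-shot model classifies one phoneme per signal; no segmentation
  or sequence decoding is attempted.
* No artifact rejection (blinks, line noise) — deliberately out of scope.
* The ANOVA grouping for the tongue-motion table (what constitutes a
  group of four) is parameterized rather than fixed, since the convention
  is ambiguous; defaults give df (1, 6).
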