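# Methods

## Problem and pipeline

The package classifies respiratory auscultation recordings into six
diagnosis classes (Bronchiectasis, Bronchiolitis, COPD, Healthy, Pneumonia,
URTI) from annotated respiratory cycles.  The pipeline is:

1. **Corpus reading** (`icbhi_io`): paired `.wav`/`.txt` files plus a
   patient-diagnosis table.  Annotation lines carry cycle start/end
   seconds and crackle/wheeze flags.  Class indices follow alphabetical
   label order so they are stable across corpora.
2. **Standardization** (`preprocessing`): polyphase resampling to
   22,050 Hz, one slice per annotated cycle (`[floor(start*rate),
   floor(end*rate))`, 0-based half-open), then zero-padding or trimming
   to exactly 6 s (132,300 samples).  Over-long cycles keep their *first*
   6 s — the inspiratory onset carries most of the cycle's information —
   and short cycles are padded with trailing silence.  Integer wav data
   is normalized to [-1, 1] at load; no per-segment gain normalization is
   applied.
3. **Features** (`features`): a shared STFT (n_fft 2048, hop 512, Hann,
   centered with reflect padding) giving T = 1 + floor(132300/512) = 259
   frames, from which three matrices are computed per segment: MFCC
   (20x259; 128-band Slaney mel filterbank, log-power, orthonormal
   DCT-II), chroma (12x259; nearest-semitone folding of bin power into 12
   pitch classes with C = 0, per-frame max-normalized, zero frames stay
   zero), and mel spectrogram (128x259, dB with an 80 dB floor below the
   maximum).  Each matrix is z-scored per segment; the channel axis is
   appended last, after normalization.  These STFT settings are the
   conventional defaults and the common choice that reproduces 259 frames
   from a 6-s segment.
4. **Models** (`model`, `kan`): see below.
5. **Protocol** (`training_eval`): stratified 70:10:20 splits (an 80/20
   outer 5-fold scheme whose training share is split 87.5/12.5 satisfies
   both ratios simultaneously), Nadam, sparse categorical cross-entropy,
   plateau learning-rate decay, early stopping, and one-vs-rest metrics.

## KAN classifier

A KAN layer replaces scalar weights with learnable univariate edge
functions

    phi_ij(x) = w_base[ij] * silu(x) + w_s[ij] * sum_m c[ijm] B_m(x),

where the B_m are the G + k degree-k B-splines on a uniform grid of G
intervals over [-1, 1], extended by k knots per side (Cox-de Boor
evaluation; partition of unity holds to 1e-12 inside the grid).  Outputs
sum the edge functions over inputs; layers compose into shapes
[n_1, ..., n_{L+1}].  The backward pass is analytic: the derivative of a
degree-k spline is a signed combination of degree-(k-1) splines.

Parameters per layer: `n_in * n_out * (G + k + 2)` — G+k spline
coefficients, one base weight and one spline scaler per edge, no biases.
With k = 3 (the selected spline order) and G = 5, the 769→6 output layer
has exactly 46,140 parameters, which is what fixes both the edge
convention and G: among standard conventions only this one reproduces the
printed output-layer count.  The published hidden-layer count (785,888
for 768→769) is not reconcilable with any standard convention for a KAN
or dense layer of those widths (768·769·10 = 5,905,920; dense would be
591,361), and the printed total differs from the sum of its own rows by
3; the hidden layer is therefore built as a 768→769 KAN layer under this
module's convention and its count is not asserted anywhere.

Grid handling: fixed uniform grid, no refinement during training (inputs
are batch-normalized directly before the KAN stage so activations sit in
the grid range); out-of-range inputs evaluate through the extended knots
without clamping.  Initialization: base weights fan-in uniform, spline
coefficients small seeded noise (sd 0.1/sqrt(n_in)), scalers 1.

## Network architecture

Both classifiers share three independent convolutional heads (no weight
sharing), one per feature matrix.  Each head: three conv blocks (32, 64,
256 filters, 3x3 kernels, batch norm + ReLU, 2x2 max pool after the
first two blocks), global average pooling, and a final batch norm,
yielding a 256-dim embedding from any input height (20, 12 or 128) with
one code path.  The three embeddings concatenate — mfcc, chroma, mspec —
into a 768-dim fusion vector.  The head internals are this package's
design (the published description names the ingredients but not the
layout); the published per-head parameter counts are consequently not
reproduction targets, while the embedding width, fusion width, and dense/
KAN classifier counts are exact.

* TriSpectraKAN: fusion → batch norm → KAN [768, 769, 6].  The hidden
  width 769 is the selected value and is honored verbatim.
* Hybrid-CNN baseline: fusion → dense 768→750→250→75→25→6 with ReLU and
  dropout (rate 0.3, unspecified upstream, configurable) between hidden
  layers; biases on every dense layer.  The published 250→75 count
  (18,225) is treated as a typo for 18,825 = 250·75 + 75 and excluded
  from checks.

The layers themselves (conv via chunked im2col + GEMM, batch norm, max
pool, dense, dropout, Nadam) are a compact NHWC numpy core with explicit
analytic backward passes, each verified against central finite
differences to 1e-6 in double precision.  Max-pool splits the gradient
evenly among tied maxima (a valid subgradient; ties are common after
ReLU).  All randomness flows through seeded `numpy` generators, so
training on one CPU thread is bit-reproducible.

## Training protocol

Defaults (the selected final values): batch size 32, initial learning
rate 0.001, Nadam, 50 epochs.  The plateau schedule halves the rate after
5 stagnant validation-loss epochs (floor 1e-5) and early stopping fires
after 10; these constants are this package's choices — the mechanisms are
prescribed upstream but not their constants.  Early stopping monitors
validation loss, and the returned model restores the weights and
batch-norm statistics of the best monitored epoch
(`TrainConfig.restore_best`, on by default) — the quantity that stops
training also selects the model.  No resampling or class
weights; imbalance is addressed only in reporting.  Splitting operates at
the segment level, which can place segments of one patient on both sides
of a split; the split helpers accept a label vector, so grouping by
patient is a caller-side choice, and the leakage risk is flagged here.

Metrics: per-class one-vs-rest TP/TN/FP/FN feed the five count formulas
(accuracy, specificity, sensitivity, precision, F1); macro values are
unweighted means over the six classes; overall accuracy is trace/total of
the confusion matrix.  Zero-denominator metrics are reported as 0 with a
warning.  Per-class ROC/AUC uses scikit-learn's `roc_curve`.

## Synthetic corpus

The generator writes complete corpora in the on-disk layout above, at the
stethoscope-native 4 kHz, so the pipeline's real resampling path is
exercised.  A breath cycle is band-limited (100-1800 Hz) noise shaped by
a raised-cosine inhale/exhale envelope and a class-specific spectral
tilt; crackles are <= 15 ms damped-sinusoid transients with
Poisson-drawn counts; wheezes are a sustained tone plus one harmonic
inside a class-specific band, added with a per-cycle probability.
Annotation flags record what was actually inserted.  Recordings tile
cycles with 0.2-0.6 s pauses; all per-recording substreams derive from
the corpus seed by counter, so regeneration is byte-identical.

The six default archetypes separate the classes through distinct wheeze
bands, crackle rates, cycle durations and tilts: COPD is wheeze-dominant
with prolonged cycles, Bronchiectasis and Pneumonia are crackle-rich,
Healthy is clean, Bronchiolitis and URTI are intermediate mixtures at
different wheeze bands.  These are engineered test fixtures with
clinically inspired contrasts, not physiological airway models; passing
the end-to-end check shows the pipeline can learn the acoustic cues it
encodes (tonal bands, transient density, spectral slope), not that it
reaches any particular accuracy on real auscultation data, which is
noisier, overlapping in its class signatures, and patient-correlated.

Default corpus size: 2 patients per class, one 60-80 s recording each
(~20 cycles per recording, ~240 six-second segments) — large enough for
the six-class end-to-end property while keeping a full training run on
one CPU core in the tens of minutes.

## Verification scale and known limitations

* The end-to-end check trains TriSpectraKAN for 20 epochs on ~240
  synthetic segments (70:10:20 split) and requires >= 90% held-out
  accuracy; the baseline is trained 2 epochs under the same harness as a
  smoke check.  Published full-corpus results (93% test accuracy and
  related tables) require the real merged corpora and full 50-epoch
  training and are out of scope here.
* Batch-norm running statistics (momentum 0.9) need a few dozen steps to
  converge; with ~6 steps per epoch the validation accuracy is
  unrepresentative for the first handful of epochs and catches up once
  the statistics settle.
* The cycle-flag calibration test checks the Poisson crackle process
  through the flag probability 1 - exp(-rate), since the annotation
  format records presence, not counts.
* The multichannel and bimodal corpus variants are unsupported; the
  reader consumes mono wav only and keeps the first channel of stereo
  files.
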