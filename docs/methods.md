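# Methods

## Problem and approach

The package classifies human activities — daily movements and falls — from a
single chest-worn tri-axial accelerometer sampled at 250 Hz.  Raw streams are
cut into non-overlapping 10 s windows (2500 samples x 3 axes, raw
dimensionless counts) with no filtering, resampling or normalisation of the
time series.  Each window is re-expressed as three 64x64x3 8-bit images that
expose complementary structure:

* **Spectrogram** (frequency domain): per axis, the squared magnitude of the
  short-time Fourier transform, `|STFT{x}(m, w)|^2`, with frames of length
  `L = round(window_seconds * fs)` starting at multiples of the hop
  `H = round(L * (1 - overlap))`; no padding or centring, so
  `n_frames = floor((N - L)/H) + 1` and the one-sided spectrum has
  `floor(L/2) + 1` bins.  Magnitudes are decibel-scaled
  (`10 log10`, floored at 1e-12 to keep a zero signal finite), the three axis
  matrices are stacked horizontally, the stack is jointly min-max normalised,
  mapped through a 256-entry perceptual colormap (viridis by default;
  grayscale available for ablation) and bilinearly resized.
* **Modified recurrence plot** (temporal self-similarity): per axis, the
  unthresholded pairwise distance matrix `D_ij = |v_i - v_j|` — the classical
  Heaviside binarisation of recurrence plots is deliberately omitted so the
  full distance structure survives.  The 2500-point series is block-averaged
  to 256 points before the O(n^2) matrix as an approximation of computing
  the full-resolution plot and resizing it.  The x, y, z matrices are
  min-max scaled per axis and become the R, G, B channels.
* **Modified multi-channel plot** (time domain): all 7500 values of the
  window are jointly min-max scaled onto the real interval [0, 255]; each
  scaled value v becomes one pixel with R = integer part, G = first-second
  decimal places, B = third-fourth decimal places (truncation on the 1e-4
  grid with a 1e-8 float guard), so `R + G/100 + B/1e4` reconstructs v to
  within 1e-4.  Each axis fills a 50x50 tile row-major; tiles are stacked
  vertically and resized.

A three-branch CNN fuses the encodings: each branch applies five blocks of
3x3 same-padding convolution + ReLU + 2x2 max pooling (spatial chain
64-32-16-8-4-2; channel schedule 32, 64, 128, 128, 64), flattens the final
2x2x64 map (256 values) and expands it to a 1024-dimensional feature.  The
three features are concatenated (3072) and classified by dense layers of 256
and `n_classes` units with softmax.  The default model has about 2.5 M
trainable parameters.  A single-input 1-D convolutional mirror of the branch
topology over the raw (2500, 3) window serves as the baseline.

## Training

Categorical cross-entropy, Adam (lr 0.005, batch size 8), 50 epochs by
default, with a reduce-on-plateau schedule that multiplies the rate by 0.7
when the validation loss has not improved for more than 3 consecutive
epochs.  The engine is a self-contained numpy implementation (im2col + GEMM
convolutions, float32, single-threaded), so a fixed seed gives
bit-reproducible runs on a given BLAS build.  Weight init is Glorot-uniform.

The returned model is the epoch with the lowest validation loss
(validation-based model selection; the test partition is never consulted).
At this learning rate the epoch-to-epoch endpoint oscillates considerably on
small datasets, and selecting on validation loss removes the dependence on
which epoch training happens to stop at.

The 1-D baseline's raw counts are divided by one fixed scale — the training
set's pooled standard deviation — before the network, exactly analogous to
dividing image pixels by 255; no per-sample normalisation or filtering is
applied anywhere.

Pooling uses floor semantics in the 1-D chain (2500 - 1250 - 625 - 312 -
156 - 78); an input that would collapse below 2 samples is rejected.

## Evaluation protocol

Splits are drawn at the *subject* level (train/validation/test subject sets
are disjoint), because inter-subject generalisation is the deployment
condition.  Metrics: top-1 and top-3 accuracy, macro one-vs-rest precision
and recall, macro one-vs-rest ROC AUC, and the full confusion matrix; macro
averaging suits the balanced class design.  Sweep harnesses repeat training
over replicate seeds (`base_seed + r`) on one fixed subject partition and
report mean (sd) per condition:

* window-size sweep — single-branch spectrogram models at 1/2/5/10 s windows
  with half-window overlap;
* method comparison — 1-D baseline, each single encoding, and the fusion
  model on the identical split;
* noise sweep — Gaussian noise added to every value of the raw *test*
  signals only (models stay fixed), images re-encoded, accuracy and
  degradation (clean minus noisy top-1) reported.  Noise levels are
  expressed as fractions of the pooled signal sigma; the conventional
  preset list is [22.5, 55, 110, 165, 220, 275] counts.

## Synthetic data generator

Real recordings of this kind are subject-private, so the package ships a
generator that emulates their statistical families rather than reproducing
any dataset.  Values are raw counts at 512 counts/g.  Archetypes:

* *periodic* (walking, stairs, jump rope, squats): fundamental near the
  cadence (walking default 1.5 Hz, i.e. ~90 steps/min) plus two harmonics
  riding on the gravity projection, with uniform +-10 % frequency jitter per
  segment, and — critically for spectral realism — an impulsive ~20 ms
  ground-contact transient once per cycle, whose harmonics extend far beyond
  the smooth gait components as heel strikes do in real data;
* *transition* (sitting down, getting up, lying down): a smooth 1-2 s
  interpolation between gravity vectors plus a movement burst;
* *transient_fall* (six fall types): quiescent pre-fall gravity, an impact
  spike of 2.2-3.5 g at a random time in the middle third of the window
  (so pre- and post-fall phases are always present), a decaying post-impact
  jostle, and a reoriented gravity vector;
* *static*: gravity plus sensor noise.

Per-subject lognormal amplitude and frequency multipliers (sd 0.1 by
default) are held fixed within subject, inducing the intra-subject
correlation that makes subject-level splitting matter.  Sensor noise is
15-20 counts (~0.03-0.04 g).  The default 15-class taxonomy assigns kinds as:
WK/UPS/DWS/JR/SQ periodic, SC/GC/LUB/LDB transition, FF/FFK/FB/LF/RF/FOB
falls, with deliberately confusable pairs (FF vs FFK differ only in impact
magnitude and post-fall pitch; LF and RF are mirror images across the x
axis).

What the generator does *not* emulate: soft-tissue and sensor-mount
artefacts, within-activity tempo drift, heterogeneous recording conditions,
and the full within-class diversity of real movement.  Synthetic classes are
more separable than real ones, so absolute accuracies here say nothing about
accuracy on real recordings; the tests demonstrate that the pipeline's
mechanics and its *relative* orderings (fusion vs single encodings, image
models vs raw 1-D under noise) behave as designed.

## Numerical choices and edge cases

* Degenerate min-max (max == min) maps to all zeros: a constant signal
  carries no contrast.
* STFT of a non-zero constant signal has a bright DC line; only a zero
  signal yields a strictly uniform spectrogram image.
* Bilinear resizing uses Pillow's float-mode filter (proper support scaling
  on downsampling) and is applied before 8-bit quantisation.
* MP digit extraction truncates on the 1e-4 tick grid with a 1e-8 absolute
  guard against float representation error.
* Argmax ties break to the lowest class index (stable sort).
* ROC AUC skips classes lacking both a positive and a negative example;
  a single-class truth raises an error.
* All randomised operations take an explicit integer seed; dataset
  simulation derives all draws from one seeded generator.

## Scaled-down study sizes

The built-in end-to-end study (used by the test suite and
`scripts/acceptance.py`) runs on one CPU in minutes, not hours, so its sizes
are deliberately compact: 4 classes spanning all signal families (WK, JR,
SC, FF), 40 subjects x 2 repetitions per class (320 segments), a 24/8/8
subject split, 10 training epochs, and 4 replicate seeds per condition.
These sizes are the package's choice of a desk-scale demonstration; the
generator's own defaults (5 repetitions per class, full 15-class taxonomy)
describe the full-scale conditions.

## Known limitations

* The numpy engine is CPU-only and sized for desk-scale experiments.
* Per-segment min-max scaling makes the MP encoding's R channel sensitive to
  range expansion under heavy additive noise, and its G/B decimal channels
  are informative only for very clean signals.
* With 10-epoch training at lr 0.005, run-to-run variance is substantial;
  replicate means (and validation-based selection) are essential.
* The spectrogram at the default 10 s window on a 10 s segment is a single
  STFT frame; the time axis then carries no information within the window.
* At desk scale the *degradation* comparison between the fusion model and
  the 1-D baseline under heavy test noise is a near-tie with large replicate
  variance: per-segment min-max scaling makes the MP branch the dominant
  noise sensitivity, and with few, well-separated classes the fusion head
  leans on that branch, while the gravity-separable synthetic classes leave
  the 1-D baseline unusually noise-tolerant.  In absolute terms the fusion
  model remains the more accurate classifier under the same noise.
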