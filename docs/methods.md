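# Methods

This note documents the modeling choices, defaults and numerical
conventions behind `harlearn`.  It covers the pipeline stage by stage, then
the synthetic-data generator and what the test suite's results do and do not
establish.

## Pipeline model

The toolkit fixes an activity-recognition chain in which only the feature
extraction stage varies: recordings are repaired and segmented identically
for every method, every method sees the same frames, and a single linear-SVM
protocol scores every feature matrix.  Anything fit from data —
normalization constants, codebooks, network weights, the SVM and its cost
parameter — is fit on the training split only.

## Segmentation

**Missing data.** Each channel's missing cells take the value of the nearest
preceding non-missing sample.  A leading gap has no preceding sample; it is
backfilled from the channel's first valid value, which avoids fabricating
zeros and keeps the operation idempotent.  A channel with no valid sample
cannot be repaired and is an error (callers drop such channels explicitly
with `drop_channels`).

**Sliding windows** are half-open, 0-based `[t, t+T)` at starts
`0, sigma, 2 sigma, ...`; trailing partial windows are discarded, making the
frame count exactly `floor((T_total - T)/sigma) + 1`.  Defaults `T=64`,
`sigma=3` correspond to roughly 2 s windows at 30 Hz.  Each frame takes the
most frequent label among its `T` timestamps; ties go to the candidate whose
last occurrence in the window is latest, a deterministic rule that favors
the activity in progress at the window's end.

**Energy windows** serve short event-centered traces (default `T=151`,
about 3 s at 50 Hz).  A peak fires at `t` when the acceleration magnitude
exceeds `theta_high` (default 1.5 g) after being below `theta_low` the
sample before.  Since a raw magnitude cannot be negative, `theta_low` is
interpreted on the gravity-subtracted signal: "below zero" means below 1 g,
so the default is `theta_low = 1.0` g, exposed as a config knob.  The window
places `T // 2` samples before the peak (odd `T` centers the peak exactly);
peaks whose window would cross a boundary are discarded, as are peaks closer
than `T // 2` samples to an earlier retained one.  Energy frames are labeled
with the label *at the peak timestamp*: a majority vote over a 3 s window
centered on a sub-second transient would almost always return the
background class, defeating the purpose of event-centered segmentation.

## Hand-crafted features

Eighteen per-channel statistics (15 time-domain, 3 frequency-related),
concatenated channel-major to an `18*S` vector and min-max normalized per
dimension with training-set constants (test values are not clipped; a
dimension constant on the training set maps to 0).  Conventions for
quantities whose bare names leave room:

- zero crossings are counted after mean-centering (`(x_t - mean)(x_{t+1} -
  mean) < 0`): raw accelerometer channels carry a gravity offset that would
  make the uncentered count degenerate;
- moments use population normalization; skewness is `m3 / m2^1.5`, kurtosis
  is reported as excess (`m4/m2^2 - 3`); both 0 for a constant series;
- autocorrelation is the lag-1 mean-centered coefficient (the smallest lag
  usable in short frames), 0 at zero variance;
- first/second-order mean is the mean of first/second discrete differences;
  its "norm" is the absolute value of that mean (the literal reading; the
  alternative mean-absolute-difference reading is noted but not used);
- spectral energy is the mean squared magnitude of the non-DC half-spectrum
  and spectral entropy the base-2 Shannon entropy of the normalized non-DC
  power spectrum, with `0 log 0 = 0`.  The DC bin duplicates the mean and is
  excluded.

Numerical degeneracy: after subtracting the mean of an exactly constant
series, O(eps) residuals remain and ratio- or sign-based statistics would
quantify roundoff noise.  A series with `sd <= 1e-13 * max|x|` is therefore
treated as constant (zero crossings, skewness, kurtosis, autocorrelation and
the spectral pair all report 0; by Parseval the non-DC power of a constant
series is exactly 0, so this is the limit value, not an approximation).

## Codebook features

Subsequences of length `w` are sampled with stride `l` (default 1 — denser
sampling is consistently better) from each channel (or, in multivariate
mode, `w x S` blocks flattened time-major).  k-means with Euclidean distance
clusters them into `N` codewords; the clustering runs 10 times from random
distinct-point initializations and the run with the minimal *sum of
Euclidean distances* between subsequences and assigned centers is kept
(ties keep the first).  Lloyd iterations update centers as centroids, stop
when assignments stabilize or after 300 iterations, and re-seed an empty
cluster with the point farthest from its assigned center.  Note the
asymmetry kept deliberately: Lloyd's updates minimize the *squared* distance
sum while the restart selection uses the unsquared sum; on
clearly clustered data both objectives elect the same partition, and the
test suite exploits exactly that regime when comparing against exhaustive
search.  When a cap on the number of subsequences is configured, clustering
operates on a seeded uniform sample.

Hard assignment increments the bin of each subsequence's nearest codeword
(ties to the lowest index) and normalizes to sum 1.  Soft assignment spreads
each subsequence over all codewords with Gaussian kernel weights
`exp(-d^2 / (2 sigma^2))`, normalized per subsequence; the histogram is the
mean over subsequences and sums to 1 exactly.  It is evaluated as a
max-shifted softmax of `-d^2/(2 sigma^2)`, which cannot underflow to an
all-zero row, so no hard-assignment fallback is ever needed.  As
`sigma -> 0` the soft histogram converges to the hard one wherever nearest
codewords are unique.

Defaults: per-channel mode with `w=24`, `N=128`, `sigma=256` (early fusion
concatenates the `S` histograms, e.g. `107 x 128 = 13,696` dimensions);
multivariate mode for triaxial data with `w=16`, `N=2048`, `sigma=4`.

## Neural extractors

All five families are implemented on a small in-package numpy layer library
with explicit forward/backward passes (exact backpropagation through time
for the recurrent layers), verified against central finite differences in
the test suite.  Shared choices:

- a single batch-normalization layer directly after the input, with
  per-sensor-channel statistics; inference uses running averages, so
  extracted features are independent of batch composition and frame order;
- valid (unpadded) convolutions with time stride 1 and non-overlapping max
  pooling with floor division — the only arithmetic consistent with the
  preset recurrent step counts (64 -> 27 with kernel 11 and pool 2;
  151 -> 60 with kernel 32 and pool 2);
- weights drawn uniform with fan-in scaling from an explicit seeded
  generator; the recurrent forget-gate bias starts at 1 so memories persist
  early in training (all other biases start at 0);
- training with ADADELTA (`rho=0.95`, `eps=1e-6`, learning-rate multiplier
  1) on categorical cross-entropy (mean squared error for the autoencoder),
  default 50 epochs at batch size 256; no dropout or other regularizers;
- the feature layer is the last activation before the softmax head
  (ReLU-activated dense of width 2000/1000/512 depending on family and
  preset); for the autoencoder it is the encoder output.

The recurrent cell follows the gate equations stated in the README: gates
are logistic functions of affine maps of the current input and the
*previous output* `c_{t-1}`; the memory update gates a tanh cell input and
the output gates a tanh of the memory.  The first recurrent layer is wired
many-to-many, the second many-to-one.

One deliberate deviation in the autoencoder: the decoder's output layer is
linear rather than ReLU.  Sensor values are signed (zero-mean oscillations
around a gravity offset), and a ReLU output could not reconstruct negative
samples at all; the encoder keeps its ReLU, so the extracted features are
unchanged in kind.

Presets: `opportunity` (T=64 multichannel; per-channel convolutions — cross-
sensor kernels degrade performance on rich channel sets), `unimib` (T=151
triaxial; one cross-sensor block), and `tiny` (one 8-kernel block, recurrent
width 16, dense width 32) used throughout the tests so that training fits in
seconds on one CPU.

## Evaluation protocol

One-vs-rest linear soft-margin SVMs (liblinear) score every feature family.
`C` is tuned by 3-fold stratified cross-validation on the training split
over the grid `10^-3..10^3`, maximizing average F1, ties to the smallest
`C`; tuning on the test set is impossible by construction.  Metrics come
from the confusion matrix with a fixed class inventory: a class with no true
positives scores F1 = 0, and a class absent from both truth and prediction
also scores 0 and still enters the average — conservative, and consistent
across folds whose class inventories differ.  Weighted F1 uses true-class
proportions.  Leave-one-subject-out cross-validation refits the entire
feature pipeline per fold and reports the unweighted mean of per-subject
metrics.

Late fusion averages two SVMs' per-class probability estimates and takes the
argmax.  Decision values are mapped to probabilities by a softmax with a
per-model temperature: each model's decision values are divided by their own
standard deviation first.  Without this, the model whose decision values
happen to live on a larger scale produces near-binary probabilities and
single-handedly decides every fused vote.  Score averaging is a benefit when
the two models are comparably strong and err on different frames; when one
model is clearly weaker, the fused score can land between the two — it is
not a dominance guarantee.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
human biomechanics.  Each activity class is a per-channel sum of up to a few
sinusoids (distinct frequencies, amplitudes and phases per class) plus
Gaussian noise and a constant gravity-like offset; labels form
piecewise-constant bouts (durations uniform in a per-class range) separated
by background (NULL) spans, scheduled greedily by largest remaining deficit
so empirical class proportions track their targets.  Missing data follows a
two-state Markov chain per channel (contiguous gaps with geometric lengths,
stationary missing fraction equal to the requested rate).  Fall-style traces
put a near-1 g baseline on one axis and impact-like bursts that rise from
below 1 g to their peak within one 50 Hz sample and decay along a quarter
sine — guaranteeing one detection per event for any peak above 1.5 g.

The end-to-end benchmark (`benchmark_spec` / `benchmark_config`) uses three
classes at 1.2 / 3.1 / 6.3 Hz with class-specific offsets, 0.05 g noise and
40 % NULL on six channels at 30 Hz; 400 s of training and 200 s of test data
are segmented into T=32 frames at stride 16 (749 / 374 frames).  Codebooks
use `w=8`, `N=16`, smoothing 0.5 (the distance scale between neighboring
codewords at these amplitudes); networks use the `tiny` preset for 10 epochs
at batch 64; the SVM uses fixed `C=1`.  These sizes keep the full
seven-method benchmark under a minute on one CPU.

What passing this benchmark shows: every feature family's full chain —
fitting on training data only, encoding both splits, classification —
separates classes whose signatures are genuinely separable, with no leakage
and no degenerate features.  What it does not show: performance on real
recordings, where classes overlap spectrally, sensors drift and disconnect,
within-class variability is high and the background class is far more
dominant; absolute scores here are near ceiling by design and say nothing
about ranking methods on real data.

## Known limitations

- The neural engine is CPU-only, float64, and sized for reference use, not
  large-scale training.
- Only the recurrent wiring described above (two layers, many-to-many then
  many-to-one) is implemented; no bidirectional or peephole variants.
- The k-means restart selection uses the unsquared distance sum while Lloyd
  updates minimize the squared sum (see above); on weakly clustered data the
  selected restart need not minimize the unsquared objective globally.
- Channel ranking uses variance only; no mutual-information or wrapper
  selection is provided.
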