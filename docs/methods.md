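# Methods

## Problem and model

The package estimates the total modified AIMS score (mAIMS; seven items —
four extremities, head/neck, trunk, global — each 0–4, summed to 0–28)
of levodopa-induced dyskinesia from two 3-axis gyroscopes (wrist and
ankle of the most affected side, 64 Hz), continuously during activities
of daily living. The estimator is a bidirectional many-to-many LSTM over
the sequence of per-window feature vectors of one *round* — one pass
through the seven-activity protocol, roughly four minutes. The working
assumption is that dyskinesia appears as short-term erratic energy in
≈1–4 Hz that interrupts the longer-term structure of voluntary movement;
a window-local regressor cannot separate the two when voluntary movement
occupies the same band (walking, ≈2 Hz), whereas the round-level temporal
context can.

## Signal processing

* **Filter**: 4th-order Butterworth band-pass, 0.5–15 Hz, applied
  forward–backward (`sosfiltfilt`) per axis on the full recording before
  windowing, so the effective response is the squared magnitude, the
  group delay is zero, and edge transients are confined to recording
  ends. Only the band itself is externally fixed; Butterworth was chosen
  for its monotone passband.
* **Windows**: non-overlapping 5 s (320 samples), anchored at each
  annotated activity segment's start; a trailing remainder < 5 s is
  dropped. Anchoring per activity guarantees single-activity windows; the
  alternative (anchoring at round start) would mix activities at
  boundaries.

## Features (13 per axis, 78 per window)

Temporal: Shannon entropy (histogram, 16 equal-width bins over
[min, max], log₂), Gini index of |x| (sorted-rank closed form), standard
deviation (population), skewness (third standardized moment), excess
kurtosis, peak-to-peak. Spectral, from a Welch PSD (periodic Hamming
taper, 128-sample segments, 50% overlap, constant detrend, one-sided
density): trapezoidal band powers over 0.5–15 Hz and 1–4 Hz, spectral
entropy of the in-band PSD normalized by log(bin count) to [0, 1],
dominant in-band frequency and its power, and the second dominant
frequency (highest peak ≥ 2 bins from the dominant, so the same lobe is
never picked twice) with its power.

Degenerate inputs are defined, not errors: a zero-variance window reports
0 for entropy, Gini, skewness and kurtosis; an all-zero spectrum reports
zero powers/entropy and both dominant frequencies at the 0.5 Hz band
edge. Ordering is frozen (sensor-major: wrist then ankle; axis-major: x,
y, z; then the 13 features) and exported as `FEATURE_NAMES_78`. The exact
histogram/Gini/PSD conventions are this package's own; other choices
(e.g. different binning) would shift feature values without changing the
pipeline's structure.

A note on symmetry: temporal features are exactly invariant under time
reversal of a window; the spectral features are invariant only up to the
one-sample alignment shift of the periodic Welch taper (relative
differences at the percent level), which the tests assert accordingly.

## Sequence model and training

Architecture: FC(78→N_h, ReLU) → bidirectional LSTM (N_l layers, N_h
states per direction, forward/backward outputs concatenated) →
FC(2N_h→N_h, ReLU) → linear head, one output per window. Dropout (rate
0.7) is applied after both fully-connected layers and between LSTM
layers, during training only.

Training: Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999), masked MSE over padded
batches of 32 round sequences, 150 epochs in the reference recipe. Padded
steps neither emit output nor advance the recurrent state (the state is
carried through the mask), so predictions are independent of batch
padding — asserted in tests. Before every epoch the order of activity
blocks inside each round is shuffled (windows within a block keep order)
so the network cannot memorize the protocol's fixed activity order;
shuffling per epoch (rather than once) maximizes that regularization.
The output bias is initialized at the training-target mean, a standard
base-score initialization that removes the slow bias-learning transient.
Predictions are clipped to [0, 28], the range where scores are
meaningful. The network, backpropagation and Adam are implemented
directly on NumPy arrays: both directions of a layer advance in one fused
recurrence (the backward direction sees time-reversed input and mask, and
the two directions' recurrent weights form a block-diagonal matrix), in
float32 for training; a float64 path supports the finite-difference
gradient checks in the test suite. Training is bit-deterministic given
the seed.

Model selection: per LOSO fold, 20% of the training rounds (whole rounds,
never split) are held out; each (N_l, N_h) grid point is trained on the
remainder and the configuration with maximum pooled window-level
validation Pearson r wins, exact ties going to the smaller model. The
reference grid is N_l ∈ {1, 2, 3} × N_h ∈ {64, 128, 192, 256, 320}
(15 points, `full_grid()`); routine runs, the examples and the acceptance
study use a reduced recipe — 30 epochs and the two-point grid
{(1, 64), (2, 64)} (`default_grid()`) — chosen as the package's standard
desk-scale configuration; it leaves the training procedure itself
unchanged.

Baseline: ordinary least squares from the same standardized 78-vectors to
the window score (features z-scored with training-fold statistics, the
identical standardizer both models use), falling back to ridge with
penalty 10⁻⁶ when the design is rank-deficient (a penalty this small
leaves well-posed fits essentially unchanged). Predictions clipped to
[0, 28].

## Evaluation

Leave-one-subject-out: one fold per subject; the test subject contributes
no training or validation rounds. Metrics: Pearson and Spearman
correlation and MAE (also as % of 28) over pooled test windows; the same
after averaging predictions and gold scores within each round;
per-activity window-level r and MAE plus the standard deviation of the
estimates within each activity segment averaged per activity type (a
stability measure — computed per segment rather than per activity type,
the reading that matches "within a single activity"); MAE split by
medication state; and an ROC for dyskinesia presence (gold ≥ 1 positive)
on round-averaged scores, with AUC by trapezoid and the operating point
maximizing min(sensitivity, specificity). Correlations are pooled across
folds, not averaged per fold. A constant gold vector makes r undefined;
it is reported as a flagged null with the reason, never as NaN.

## Synthetic cohort generator

The generator defines the study conditions: 15 subjects (two of whom
perform only three rounds, giving 58 rounds), 4 rounds × 7 ADLs of
15–60 s at 64 Hz, first round OFF and later rounds ON for full-protocol
subjects. Latent severity: a per-subject ON-state peak drawn uniformly
from 4–24 mAIMS points, decaying mildly over late rounds; OFF rounds keep
0–15% of the peak (wearing-off dyskinesia). Per-activity severity wobbles
around the round level (sd 0.5). Signals, in deg/s: per-activity
voluntary movement (walking: ≈2 Hz fundamental plus first harmonic,
dominant on the ankle at 60 deg/s RMS, partially periodic on the wrist;
resting: low-amplitude 0.5–3 Hz noise; other ADLs: burst-enveloped
0.5–5 Hz noise at 20–35 deg/s RMS); additive dyskinesia as 1–4 Hz
random-phase noise with RMS = (severity/28) × full-scale (45 deg/s wrist,
28 deg/s ankle) split randomly across axes; OFF-state tremor as a
frequency-jittered 4–6 Hz sinusoid independent of severity. Raters report
integer scores = clip(round(severity + N(0, 1)), 0, 28); their mean is
the gold standard. The wrist walking amplitudes are calibrated so that,
at defaults, the pooled correlation between severity and the wrist
(1–4 Hz)/(0.5–15 Hz) band-power ratio per activity segment stays ≥ 0.6
while the walking confound remains fully present on the ankle.

What the generator does *not* emulate: biomechanical coupling between
joints, accelerometer channels, per-extremity sub-score dynamics (a
single latent total-mAIMS value drives all sensors), activity
misannotation, sensor artifacts, and the weaker, noisier
severity–amplitude relation of real recordings. Passing recovery tests
therefore shows the pipeline recovers the structure it assumes — a
monotone severity→band-power map with spectral confounds — not clinical
accuracy; published clinical correlations cannot be reproduced from
synthetic data and are out of scope here.

## Numerical and design notes

* Master seeds fan out through `numpy.random.SeedSequence`; every fold,
  initialization and shuffle stream derives from them and is logged in
  the report (`folds`), making whole reports byte-reproducible.
* The gold score is always derived from the two rater scores, never
  serialized, so the two can never disagree on disk.
* Round-level MAE is *not* asserted to be below window-level MAE —
  averaging does not force that; only the pair count (one per round) is
  contractual.
* ROC requires both classes; a cohort without any dyskinesia-free round
  yields a logged, absent ROC rather than an error in the full report.
* Time convention: seconds from session start, half-open activity
  segments [start, end); axes are named x, y, z in file column order with
  no reorientation.

## Known limitations

Training on CPU at the full 15-point grid and 150 epochs is slow (hours);
the reduced recipe is the practical default. The linear baseline is
unrealistically strong on synthetic cohorts because the severity→RMS map
is linear by construction; the qualitative LSTM-vs-linear ordering on
walking, not the absolute gap, is the transferable observation.
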