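# dyskest

Severity estimation of levodopa-induced dyskinesia during activities of
daily living (ADL), from two wearable gyroscopes and a bidirectional LSTM
sequence regressor.

People with mid- to advanced-stage Parkinson's disease commonly develop
dyskinesias — involuntary, often choreiform movements peaking at maximal
levodopa effect. Adjusting medication requires knowing how severe these
movements are over a full ON/OFF cycle, not just during a clinic snapshot.
`dyskest` implements a sensor-based estimator of the total modified
Abnormal Involuntary Movement Scale score (mAIMS, 0–28) from 3-axis
angular-velocity streams recorded at 64 Hz on the wrist and ankle of the
most affected side, while the wearer performs ordinary activities
(walking, resting, cutting food, dressing, drinking, unpacking groceries,
hair brushing).

The hard part is that dyskinetic movement (≈1–4 Hz) overlaps spectrally
with voluntary movement — walking in particular has a ≈2 Hz fundamental —
so window-by-window regression confuses the two. The estimator therefore
models the *temporal context* of a whole round of activities.

## Pipeline

1. **Band-pass filter** each axis, 0.5–15 Hz (4th-order Butterworth,
   zero-phase), removing drift and high-frequency noise.
2. **Segment** into non-overlapping 5-s windows (320 samples), anchored at
   activity starts so no window spans two activities.
3. **Featurize**: 13 features per axis — Shannon entropy, Gini index,
   standard deviation, skewness, kurtosis, peak-to-peak; 0.5–15 Hz and
   1–4 Hz band powers, spectral entropy, dominant and second-dominant
   frequency with their powers (Welch PSD) — giving a descriptor
   **fv ∈ ℝ⁷⁸** per window (13 × 3 axes × 2 sensors).
4. **Regress**: the feature-vector sequence FV⁽ʳ⁾ ∈ ℝ^{N_w×78} of a round
   is mapped many-to-many by FC(78→N_h, ReLU) → bidirectional LSTM
   (N_l layers, N_h states) → FC(ReLU) → linear head, one score ŷ per
   window, trained with Adam on masked MSE (lr 10⁻³, batches of 32
   sequences, dropout 0.7, activity-block order shuffled every epoch).
   An OLS linear regression on the same standardized features is the
   baseline. The recurrent network, its backpropagation and Adam are
   implemented directly on NumPy arrays (gradient-checked against finite
   differences).
5. **Evaluate** leave-one-subject-out (LOSO): per fold, a validation split
   (20% of training rounds) selects (N_l, N_h) from a grid by Pearson r;
   metrics are reported per 5-s window and per round (window estimates
   averaged), per activity, per medication state, plus an ROC analysis
   where gold mAIMS ≥ 1 defines dyskinesia presence.

No clinical recordings ship with the package; a seeded synthetic cohort
generator (`dyskest.synth`) reproduces the structure such a study
produces — 15 subjects × 3–4 rounds × 7 ADLs of 15–60 s, OFF→ON
medication cycling, 1–4 Hz dyskinesia whose amplitude grows with a latent
severity, OFF-state 4–6 Hz rest tremor, and two noisy integer raters whose
average is the gold standard.

## Worked example

`examples/03_train_and_evaluate.py` runs the full pipeline on a reduced
cohort (6 subjects × 3 rounds, seed 42) in a few minutes on one core:

```
bilstm             window r=0.84 MAE=2.67 (9.5%) | round r=0.87 MAE=2.45
linear_regression  window r=0.91 MAE=1.97 (7.0%) | round r=0.99 MAE=1.09

per-activity window-level r (LSTM vs linear):
  ...
  walking              +0.76 vs +0.64

round-level dyskinesia detection (gold >= 1): LSTM AUC = 0.88 at
threshold 3.51 (sens 0.79 / spec 1.00)
```

`window r` / `round r` are Pearson correlations between estimated and
gold severity over 5-s windows and round averages; MAE is in mAIMS points
(percentage of the 28-point scale in parentheses). On this synthetic
cohort the mostly-linear severity→amplitude map makes the OLS baseline
strong overall, but the walking row shows the characteristic gap: the
linear model is degraded by the in-band walking rhythm while the LSTM
uses round context to stay accurate. The other examples show cohort
simulation (`01`) and per-feature relevance ranking (`02`).

A thin CLI wraps the same functions:

```bash
dyskest simulate --out cohort/ --seed 1
dyskest preprocess --in cohort/ --out features.csv
dyskest evaluate --in cohort/ --out report.json --seed 1
dyskest run-all --config run.yaml
```

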