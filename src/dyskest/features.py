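"""Temporal/spectral window features and the 78-dimensional descriptor.

From each 5-s, 320-sample axis we extract 13 features — six temporal
(Shannon entropy, Gini index, standard deviation, skewness, kurtosis,
peak-to-peak) and seven spectral (0.5-15 Hz band power, 1-4 Hz band power,
spectral entropy, dominant frequency and its power, second dominant
frequency and its power).  With 3 axes and 2 sensors this yields a
78-element descriptor per window, ordered sensor-major (wrist then ankle),
axis-major (x, y, z), features in the fixed order below.

Definitions
-----------
* Shannon entropy: histogram entropy, 16 equal-width bins over
  ``[min, max]``, log base 2.
* Gini index: Gini coefficient of ``|x|`` via the sorted-rank closed form.
* Skewness / kurtosis: sample third standardized moment and excess (Fisher)
  fourth standardized moment.
* PSD: Welch, Hamming window of 128 samples, 50% overlap, one-sided,
  density scaling; band powers by trapezoidal integration over the closed
  band.
* Spectral entropy: Shannon entropy of the normalized in-band (0.5-15 Hz)
  PSD, divided by log of the bin count, so it lies in [0, 1].
* Second dominant frequency: highest in-band peak at least 2 bins from the
  dominant bin.

Zero-variance windows are a defined degenerate case: entropy, Gini,
skewness and kurtosis are 0; an all-zero spectrum reports zero powers and
both dominant frequencies at the 0.5 Hz band edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io import LabeledDataset
from .preprocess import RoundSequence, Window

WINDOW_SAMPLES = 320
FS = 64.0
FULL_BAND = (0.5, 15.0)
DYSK_BAND = (1.0, 4.0)
N_BINS_ENTROPY = 16
WELCH_NPERSEG = 128

TEMPORAL_NAMES = (
    "shannon_entropy",
    "gini_index",
    "std",
    "skewness",
    "kurtosis",
    "peak_to_peak",
)
SPECTRAL_NAMES = (
    "power_0p5_15",
    "power_1_4",
    "spectral_entropy",
    "f_dom",
    "p_dom",
    "f_dom2",
    "p_dom2",
)
FEATURE_NAMES_13 = TEMPORAL_NAMES + SPECTRAL_NAMES

AXES = ("x", "y", "z")
SENSORS = ("wrist", "ankle")

#: Frozen 78-name ordering: sensor-major, axis-major, then the 13 features.
FEATURE_NAMES_78 = tuple(
    f"{sensor}_{axis}_{name}"
    for sensor in SENSORS
    for axis in AXES
    for name in FEATURE_NAMES_13
)
N_FEATURES = len(FEATURE_NAMES_78)


@dataclass
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray


def psd(x: np.ndarray, fs: float = FS) -> Spectrum:
    """One-sided Welch power spectral density of a 320-sample window axis."""
    x = np.asarray(x, dtype=float)
    if x.size != WINDOW_SAMPLES:
        raise ValueError(f"expected {WINDOW_SAMPLES} samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    freqs, power = signal.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=WELCH_NPERSEG,
        noverlap=WELCH_NPERSEG // 2,
        detrend="constant",
        scaling="density",
    )
    return Spectrum(freqs=freqs, power=power)


# ---------------------------------------------------------------------------
# temporal features


def temporal_features(x: np.ndarray) -> np.ndarray:
    """The six temporal features of one window axis, in TEMPORAL_NAMES order."""
    x = np.asarray(x, dtype=float)
    ptp = float(np.max(x) - np.min(x))
    if ptp == 0.0:  # constant signal: all six degenerate to 0
        return np.zeros(6)
    counts, _ = np.histogram(x, bins=N_BINS_ENTROPY, range=(np.min(x), np.max(x)))
    p = counts[counts > 0] / x.size
    entropy = float(-np.sum(p * np.log2(p)))
    g = np.sort(np.abs(x))
    s = g.sum()
    if s == 0.0:
        gini = 0.0
    else:
        n = g.size
        gini = float(2.0 * np.sum(np.arange(1, n + 1) * g) / (n * s) - (n + 1) / n)
    return np.array(
        [
            entropy,
            gini,
            float(np.std(x)),
            float(stats.skew(x)),
            float(stats.kurtosis(x)),  # excess kurtosis
            ptp,
        ]
    )


# ---------------------------------------------------------------------------
# spectral features


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)


def band_power(spec: Spectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over the closed band."""
    m = _band_mask(spec.freqs, band)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(spec.power[m], spec.freqs[m]))


def spectral_features(spec: Spectrum) -> np.ndarray:
    """The seven spectral features of one window axis, in SPECTRAL_NAMES order."""
    m = _band_mask(spec.freqs, FULL_BAND)
    in_band = spec.power[m]
    in_freqs = spec.freqs[m]
    total = band_power(spec, FULL_BAND)
    if total == 0.0 or np.all(in_band == 0.0):
        return np.array([0.0, 0.0, 0.0, FULL_BAND[0], 0.0, FULL_BAND[0], 0.0])
    p14 = band_power(spec, DYSK_BAND)
    p = in_band / in_band.sum()
    nz = p > 0
    sent = float(-np.sum(p[nz] * np.log(p[nz])) / np.log(p.size))
    i1 = int(np.argmax(in_band))
    far = np.abs(np.arange(in_band.size) - i1) >= 2
    if far.any():
        i2 = int(np.flatnonzero(far)[np.argmax(in_band[far])])
    else:
        i2 = i1
    return np.array(
        [
            total,
            p14,
            sent,
            float(in_freqs[i1]),
            float(in_band[i1]),
            float(in_freqs[i2]),
            float(in_band[i2]),
        ]
    )


def axis_features(x: np.ndarray, fs: float = FS) -> np.ndarray:
    """All 13 features of one axis (temporal then spectral)."""
    return np.concatenate([temporal_features(x), spectral_features(psd(x, fs))])


def extract_window_features(window: Window) -> np.ndarray:
    """The 78-element descriptor of one two-sensor window (FEATURE_NAMES_78 order)."""
    parts = []
    for sensor in SENSORS:
        data = getattr(window, sensor)
        for ax in range(3):
            parts.append(axis_features(data[ax]))
    return np.concatenate(parts)


# -- batched extraction ------------------------------------------------------
# featurize_rounds routes through vectorized versions of the same formulas
# (one Welch call and one histogram pass for all axes at once); equality with
# the per-window path is asserted in the test suite.


def _temporal_batch(X: np.ndarray) -> np.ndarray:
    """Vectorized temporal features for rows of ``X`` ((n, 320) -> (n, 6))."""
    n, w = X.shape
    mn = X.min(axis=1)
    mx = X.max(axis=1)
    ptp = mx - mn
    ok = ptp > 0.0
    out = np.zeros((n, 6))
    if ok.any():
        Xo = X[ok]
        span = ptp[ok][:, None]
        # shared bincount over row-offset bin indices
        bins = np.minimum(
            ((Xo - mn[ok][:, None]) / span * N_BINS_ENTROPY).astype(np.intp),
            N_BINS_ENTROPY - 1,
        )
        offsets = np.arange(ok.sum())[:, None] * N_BINS_ENTROPY
        counts = np.bincount(
            (bins + offsets).ravel(), minlength=ok.sum() * N_BINS_ENTROPY
        ).reshape(-1, N_BINS_ENTROPY)
        p = counts / w
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
        g = np.sort(np.abs(Xo), axis=1)
        s = g.sum(axis=1)
        ranks = np.arange(1, w + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            gini = np.where(
                s > 0, 2.0 * (g * ranks).sum(axis=1) / (w * s) - (w + 1) / w, 0.0
            )
        out[ok, 0] = ent
        out[ok, 1] = gini
        out[ok, 2] = np.std(Xo, axis=1)
        out[ok, 3] = stats.skew(Xo, axis=1)
        out[ok, 4] = stats.kurtosis(Xo, axis=1)
        out[ok, 5] = ptp[ok]
    return out


def _spectral_batch(X: np.ndarray, fs: float = FS) -> np.ndarray:
    """Vectorized spectral features for rows of ``X`` ((n, 320) -> (n, 7))."""
    freqs, power = signal.welch(
        X, fs=fs, window="hamming", nperseg=WELCH_NPERSEG,
        noverlap=WELCH_NPERSEG // 2, detrend="constant", scaling="density",
        axis=-1,
    )
    m = _band_mask(freqs, FULL_BAND)
    in_f = freqs[m]
    P = power[:, m]
    n = X.shape[0]
    out = np.zeros((n, 7))
    out[:, 3] = FULL_BAND[0]
    out[:, 5] = FULL_BAND[0]
    total = np.trapezoid(P, in_f, axis=1)
    ok = (total > 0.0) & (P.sum(axis=1) > 0.0)
    if not ok.any():
        return out
    Po = P[ok]
    m14 = _band_mask(in_f, DYSK_BAND)
    out[ok, 0] = total[ok]
    out[ok, 1] = np.trapezoid(Po[:, m14], in_f[m14], axis=1)
    p = Po / Po.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[ok, 2] = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1) / np.log(p.shape[1])
    i1 = np.argmax(Po, axis=1)
    out[ok, 3] = in_f[i1]
    out[ok, 4] = Po[np.arange(Po.shape[0]), i1]
    far = np.abs(np.arange(Po.shape[1])[None, :] - i1[:, None]) >= 2
    masked = np.where(far, Po, -np.inf)
    i2 = np.argmax(masked, axis=1)
    out[ok, 5] = in_f[i2]
    out[ok, 6] = Po[np.arange(Po.shape[0]), i2]
    return out


def extract_features_batch(windows: list[Window]) -> np.ndarray:
    """78-feature descriptors for many windows at once ((n, 78))."""
    if not windows:
        return np.zeros((0, N_FEATURES))
    # rows ordered window-major, then sensor-major, axis-major
    rows = np.stack(
        [getattr(w, sensor)[ax] for w in windows for sensor in SENSORS for ax in range(3)]
    )
    feats = np.hstack([_temporal_batch(rows), _spectral_batch(rows)])
    return feats.reshape(len(windows), N_FEATURES)


def featurize_rounds(sequences: list[RoundSequence]) -> list[RoundSequence]:
    """Fill each round's ``features`` array ((n_windows, 78)); returns its input."""
    for seq in sequences:
        seq.features = extract_features_batch(seq.windows)
    return sequences


def feature_table(sequences: list[RoundSequence]) -> pd.DataFrame:
    """One row per window: keys + gold + the 78 features (for CSV export)."""
    rows = []
    for seq in sequences:
        if seq.features is None:
            raise ValueError("sequences must be featurized first")
        for w, fv in zip(seq.windows, seq.features):
            rows.append(
                {
                    "subject_id": w.subject_id,
                    "round_index": w.round_index,
                    "activity": w.activity,
                    "start_s": w.start_s,
                    "medication_state": w.medication_state,
                    "gold": w.gold,
                    **dict(zip(FEATURE_NAMES_78, fv)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-feature relevance


def feature_relevance(sequences: list[RoundSequence]) -> pd.DataFrame:
    """Pearson correlation of each of the 13 features with the gold score.

    Feature values are averaged across the three axes of each sensor, then
    across the windows of each round, giving one value per feature per
    sensor per round; these are correlated with the per-round mean gold
    score.  Returns 13 rows per sensor with columns
    ``(sensor, feature, r, p, note)``; a zero-variance feature is reported
    with missing ``r`` and the reason in ``note``.
    """
    seqs = [s for s in sequences if s.n_windows > 0]
    if len(seqs) < 3:
        raise ValueError("feature relevance requires at least 3 non-empty rounds")
    per_round = {sensor: [] for sensor in SENSORS}
    gold = []
    for seq in seqs:
        fv = seq.features.reshape(seq.n_windows, len(SENSORS), len(AXES), len(FEATURE_NAMES_13))
        # mean over the 3 axes, then over the round's windows
        for si, sensor in enumerate(SENSORS):
            per_round[sensor].append(fv[:, si].mean(axis=1).mean(axis=0))
        gold.append(float(seq.gold.mean()))
    gold_arr = np.array(gold)
    rows = []
    for sensor in SENSORS:
        mat = np.vstack(per_round[sensor])  # (n_rounds, 13)
        for j, name in enumerate(FEATURE_NAMES_13):
            col = mat[:, j]
            if np.std(col) == 0.0 or np.std(gold_arr) == 0.0:
                rows.append(
                    {"sensor": sensor, "feature": name, "r": np.nan, "p": np.nan,
                     "note": "zero variance"}
                )
            else:
                r, p = stats.pearsonr(col, gold_arr)
                rows.append({"sensor": sensor, "feature": name, "r": r, "p": p, "note": ""})
    return pd.DataFrame(rows)


def featurize_dataset(dataset: LabeledDataset) -> list[RoundSequence]:
    """Filter, segment, group and featurize a dataset in one call."""
    from .preprocess import filter_dataset, group_rounds, segment

    windows = segment(filter_dataset(dataset))
    return featurize_rounds(group_rounds(windows))
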