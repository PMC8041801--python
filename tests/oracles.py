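"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the mathematical definitions, deliberately
avoiding the code paths (and, where practical, the library calls) used by
the package itself.
"""

from __future__ import annotations

import numpy as np


# -- temporal ----------------------------------------------------------------


def entropy_oracle(x: np.ndarray, n_bins: int = 16) -> float:
    """Histogram Shannon entropy (log2), equal-width bins over [min, max]."""
    lo, hi = float(min(x)), float(max(x))
    if hi == lo:
        return 0.0
    counts = [0] * n_bins
    for v in x:
        b = int((v - lo) / (hi - lo) * n_bins)
        if b == n_bins:
            b -= 1
        counts[b] += 1
    n = len(x)
    ent = 0.0
    for c in counts:
        if c:
            p = c / n
            ent -= p * np.log2(p)
    return ent


def gini_oracle(x: np.ndarray) -> float:
    """Gini coefficient of |x| via the mean-absolute-difference definition."""
    g = np.abs(np.asarray(x, dtype=float))
    mu = g.mean()
    if mu == 0.0:
        return 0.0
    mad = np.abs(np.subtract.outer(g, g)).mean()
    return float(mad / (2.0 * mu))


def std_oracle(x: np.ndarray) -> float:
    m = sum(x) / len(x)
    return float(np.sqrt(sum((v - m) ** 2 for v in x) / len(x)))


def skew_oracle(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0.0:
        return 0.0
    m3 = ((x - m) ** 3).mean()
    return float(m3 / m2**1.5)


def kurtosis_oracle(x: np.ndarray) -> float:
    """Excess (Fisher) kurtosis."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0.0:
        return 0.0
    m4 = ((x - m) ** 4).mean()
    return float(m4 / m2**2 - 3.0)


def ptp_oracle(x: np.ndarray) -> float:
    return float(max(x) - min(x))


# -- spectral ----------------------------------------------------------------


def welch_oracle(x: np.ndarray, fs: float = 64.0, nperseg: int = 128):
    """Welch PSD from first principles: periodic Hamming taper, 50% overlap,
    per-segment constant detrend, one-sided density scaling, mean over
    segments."""
    x = np.asarray(x, dtype=float)
    step = nperseg // 2
    n = np.arange(nperseg)
    w = 0.54 - 0.46 * np.cos(2.0 * np.pi * n / nperseg)  # periodic Hamming
    scale = 1.0 / (fs * (w**2).sum())
    periodograms = []
    start = 0
    while start + nperseg <= x.size:
        seg = x[start : start + nperseg]
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * w)
        p = (spec.real**2 + spec.imag**2) * scale
        p[1:-1] *= 2.0  # one-sided, except DC and Nyquist
        periodograms.append(p)
        start += step
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, np.mean(periodograms, axis=0)


def trapezoid_oracle(y: np.ndarray, x: np.ndarray) -> float:
    total = 0.0
    for k in range(len(x) - 1):
        total += 0.5 * (y[k] + y[k + 1]) * (x[k + 1] - x[k])
    return float(total)


def spectral_features_oracle(freqs: np.ndarray, power: np.ndarray,
                             full_band=(0.5, 15.0), dysk_band=(1.0, 4.0)):
    """The seven spectral features computed with explicit loops."""
    sel = [k for k, f in enumerate(freqs) if full_band[0] - 1e-12 <= f <= full_band[1] + 1e-12]
    in_f = freqs[sel]
    in_p = power[sel]
    if all(p == 0.0 for p in in_p):
        return np.array([0.0, 0.0, 0.0, full_band[0], 0.0, full_band[0], 0.0])
    total = trapezoid_oracle(in_p, in_f)
    sel14 = [k for k, f in enumerate(in_f) if dysk_band[0] - 1e-12 <= f <= dysk_band[1] + 1e-12]
    p14 = trapezoid_oracle(in_p[sel14], in_f[sel14])
    s = in_p.sum()
    ent = 0.0
    for p in in_p:
        if p > 0:
            q = p / s
            ent -= q * np.log(q)
    ent /= np.log(len(in_p))
    i1 = max(range(len(in_p)), key=lambda k: in_p[k])
    far = [k for k in range(len(in_p)) if abs(k - i1) >= 2]
    i2 = max(far, key=lambda k: in_p[k]) if far else i1
    return np.array([total, p14, ent, in_f[i1], in_p[i1], in_f[i2], in_p[i2]])


def axis_features_oracle(x: np.ndarray, fs: float = 64.0) -> np.ndarray:
    """All 13 per-axis features from the independent implementations."""
    temporal = np.array(
        [
            entropy_oracle(x),
            gini_oracle(x),
            std_oracle(x),
            skew_oracle(x),
            kurtosis_oracle(x),
            ptp_oracle(x),
        ]
    )
    if ptp_oracle(x) == 0.0:
        temporal[:] = 0.0
    freqs, power = welch_oracle(x, fs=fs)
    return np.concatenate([temporal, spectral_features_oracle(freqs, power)])


# -- metrics -----------------------------------------------------------------


def pearson_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Direct covariance-formula Pearson correlation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    num = n * (a * b).sum() - a.sum() * b.sum()
    den = np.sqrt(n * (a**2).sum() - a.sum() ** 2) * np.sqrt(
        n * (b**2).sum() - b.sum() ** 2
    )
    return float(num / den)


def _avg_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    k = 0
    while k < x.size:
        j = k
        while j + 1 < x.size and x[order[j + 1]] == x[order[k]]:
            j += 1
        ranks[order[k : j + 1]] = (k + j) / 2.0 + 1.0
        k = j + 1
    return ranks


def spearman_oracle(a: np.ndarray, b: np.ndarray) -> float:
    return pearson_oracle(_avg_ranks(np.asarray(a, float)), _avg_ranks(np.asarray(b, float)))


def mae_oracle(a: np.ndarray, b: np.ndarray) -> float:
    return float(sum(abs(float(x) - float(y)) for x, y in zip(a, b)) / len(a))


def mean_oracle(x) -> float:
    return float(sum(x) / len(x))


def auc_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic over positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    u = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos) * len(neg))


def std_of(x) -> float:
    return std_oracle(list(x))
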