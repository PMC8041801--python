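"""Band-pass filtering and non-overlapping 5-s segmentation.

The raw gyroscope streams are passed through a zero-phase 0.5-15 Hz
band-pass filter (4th-order Butterworth applied forward-backward) to remove
drift and high-frequency noise, then cut into non-overlapping 5-s windows.
Windows are anchored at the start of each annotated activity segment so a
window never spans two activities; a trailing remainder shorter than the
window is dropped.  Each window inherits its segment's activity label,
medication state and gold-standard severity score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import LabeledDataset, SensorRecording

logger = logging.getLogger(__name__)

WINDOW_S = 5.0
BAND = (0.5, 15.0)
FILTER_ORDER = 4

__all__ = ["Window", "RoundSequence", "bandpass", "filter_dataset", "segment", "group_rounds"]


def bandpass(
    x: np.ndarray,
    fs: float = 64.0,
    low: float = BAND[0],
    high: float = BAND[1],
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a 1-axis stream.

    Applied forward and backward (``sosfiltfilt``), so the effective
    attenuation is the squared magnitude response and the group delay is
    zero.  Output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for a {high} Hz band edge")
    min_len = 3 * 2 * (order + 1)  # sosfiltfilt default padding requirement
    if x.size <= min_len:
        raise ValueError(f"signal too short to filter: {x.size} <= {min_len} samples")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def filter_dataset(dataset: LabeledDataset) -> LabeledDataset:
    """Return a copy of the dataset with every recording band-pass filtered per axis."""
    filtered = {}
    for key, rec in dataset.recordings.items():
        gyro = np.vstack([bandpass(ax, fs=rec.sampling_rate) for ax in rec.gyro])
        filtered[key] = SensorRecording(
            subject_id=rec.subject_id, site=rec.site,
            sampling_rate=rec.sampling_rate, t=rec.t.copy(), gyro=gyro,
        )
    return LabeledDataset(recordings=filtered, annotations=dict(dataset.annotations))


@dataclass
class Window:
    """One 5-s two-sensor window, fully inside a single activity segment."""

    subject_id: str
    round_index: int
    activity: str
    start_s: float
    medication_state: str
    gold: float
    wrist: np.ndarray  # (3, 320)
    ankle: np.ndarray  # (3, 320)

    @property
    def n_samples(self) -> int:
        return self.wrist.shape[1]


@dataclass
class RoundSequence:
    """Time-ordered windows of one round; the sequence model's unit of input."""

    subject_id: str
    round_index: int
    medication_state: str
    windows: list[Window]
    features: np.ndarray | None = None  # (n_windows, 78) once featurized

    @property
    def gold(self) -> np.ndarray:
        return np.array([w.gold for w in self.windows])

    @property
    def activities(self) -> list[str]:
        return [w.activity for w in self.windows]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def activity_blocks(self) -> list[np.ndarray]:
        """Indices of consecutive same-activity windows, in time order."""
        blocks: list[list[int]] = []
        for i, w in enumerate(self.windows):
            if blocks and self.windows[i - 1].activity == w.activity:
                blocks[-1].append(i)
            else:
                blocks.append([i])
        return [np.array(b) for b in blocks]


def _slice(rec: SensorRecording, start_s: float, n: int) -> np.ndarray:
    i0 = int(np.searchsorted(rec.t, start_s - 0.5 / rec.sampling_rate))
    return rec.gyro[:, i0 : i0 + n]


def segment(dataset: LabeledDataset, win_s: float = WINDOW_S) -> list[Window]:
    """Tile every activity segment with non-overlapping windows of ``win_s`` seconds.

    Windows start at the segment start; the remainder shorter than ``win_s``
    is dropped.  Wrist and ankle windows are cut at identical times.
    """
    windows: list[Window] = []
    for (subject, rnd), ann in sorted(dataset.annotations.items()):
        wrist = dataset.recordings[(subject, "wrist")]
        ankle = dataset.recordings[(subject, "ankle")]
        n_win_samples = round(win_s * wrist.sampling_rate)
        for seg in ann.segments:
            n_fit = int(seg.duration_s / win_s + 1e-9)
            if n_fit == 0:
                logger.info(
                    "segment %s/%s round %d shorter than %gs; no windows",
                    subject, seg.activity, rnd, win_s,
                )
                continue
            for k in range(n_fit):
                start = seg.start_s + k * win_s
                w = _slice(wrist, start, n_win_samples)
                a = _slice(ankle, start, n_win_samples)
                if w.shape[1] < n_win_samples or a.shape[1] < n_win_samples:
                    break  # segment extends past the recording tail
                windows.append(
                    Window(
                        subject_id=subject,
                        round_index=rnd,
                        activity=seg.activity,
                        start_s=start,
                        medication_state=ann.medication_state,
                        gold=seg.gold,
                        wrist=w,
                        ankle=a,
                    )
                )
    return windows


def group_rounds(windows: list[Window]) -> list[RoundSequence]:
    """Group windows into per-round time-ordered sequences."""
    by_round: dict[tuple[str, int], list[Window]] = {}
    states: dict[tuple[str, int], str] = {}
    for w in windows:
        key = (w.subject_id, w.round_index)
        by_round.setdefault(key, []).append(w)
        states[key] = w.medication_state
    sequences = []
    for key in sorted(by_round):
        ws = sorted(by_round[key], key=lambda w: w.start_s)
        sequences.append(
            RoundSequence(
                subject_id=key[0], round_index=key[1],
                medication_state=states[key], windows=ws,
            )
        )
    return sequences


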