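"""Data model and on-disk formats for recordings, annotations and cohorts.

A *recording* is one sensor's continuous 3-axis angular-velocity stream for
one subject session (CSV with ``#``-prefixed metadata lines).  A *round
annotation* carries the activity segments of one ~4-min round of activities
of daily living together with two raters' total mAIMS scores per activity
and the medication state (JSON).  The gold-standard severity score of a
segment is the arithmetic mean of the two rater scores; it is always derived,
never serialized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SITES = ("wrist", "ankle")
MAIMS_MAX = 28.0
DEFAULT_FS = 64.0

__all__ = [
    "SITES",
    "MAIMS_MAX",
    "DEFAULT_FS",
    "SensorRecording",
    "Segment",
    "RoundAnnotation",
    "LabeledDataset",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "assemble_dataset",
    "write_cohort",
    "load_cohort",
]


class ParseError(ValueError):
    """A file violated the documented recording/annotation format."""


@dataclass
class SensorRecording:
    """One sensor's timestamped 3-axis gyroscope stream (deg/s)."""

    subject_id: str
    site: str
    sampling_rate: float
    t: np.ndarray          # seconds from session start, strictly increasing
    gyro: np.ndarray       # shape (3, N); axes x, y, z

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def validate(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.gyro.shape != (3, self.t.size):
            raise ValueError(
                f"gyro shape {self.gyro.shape} inconsistent with {self.t.size} timestamps"
            )
        if not np.all(np.isfinite(self.t)):
            row = int(np.flatnonzero(~np.isfinite(self.t))[0])
            raise ParseError(f"non-finite timestamp at row {row}")
        if not np.all(np.isfinite(self.gyro)):
            row = int(np.flatnonzero(~np.isfinite(self.gyro).all(axis=0))[0])
            raise ParseError(f"non-finite sample at row {row}")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            row = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise ParseError(f"time not strictly increasing at row {row}")


@dataclass
class Segment:
    """One activity trial within a round; half-open time support [start, end)."""

    activity: str
    start_s: float
    end_s: float
    rater1: float
    rater2: float

    @property
    def gold(self) -> float:
        """Gold-standard score: mean of the two raters' total mAIMS."""
        return (self.rater1 + self.rater2) / 2.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def validate(self) -> None:
        if not (self.end_s > self.start_s):
            raise ValueError(f"segment {self.activity!r}: end_s must exceed start_s")
        for name, score in (("rater1", self.rater1), ("rater2", self.rater2)):
            if not (0.0 <= score <= MAIMS_MAX):
                raise ValueError(
                    f"segment {self.activity!r}: {name} score {score} outside [0, {MAIMS_MAX:g}]"
                )


@dataclass
class RoundAnnotation:
    subject_id: str
    round_index: int
    medication_state: str  # "ON" | "OFF"
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.medication_state not in ("ON", "OFF"):
            raise ValueError(f"medication_state must be ON or OFF, got {self.medication_state!r}")
        for seg in self.segments:
            seg.validate()
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"overlapping segments in {self.subject_id} round {self.round_index}: "
                    f"{a.activity!r} [{a.start_s:g}, {a.end_s:g}) and "
                    f"{b.activity!r} [{b.start_s:g}, {b.end_s:g})"
                )

    @property
    def start_s(self) -> float:
        return self.segments[0].start_s if self.segments else 0.0

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s if self.segments else 0.0


@dataclass
class LabeledDataset:
    """Cross-referenced recordings + annotations for a cohort.

    ``recordings`` is keyed by ``(subject_id, site)`` and ``annotations`` by
    ``(subject_id, round_index)``.
    """

    recordings: dict[tuple[str, str], SensorRecording]
    annotations: dict[tuple[str, int], RoundAnnotation]

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.annotations})

    @property
    def n_rounds(self) -> int:
        return len(self.annotations)

    def rounds_of(self, subject_id: str) -> list[RoundAnnotation]:
        return [a for (s, _), a in sorted(self.annotations.items()) if s == subject_id]

    def total_annotated_seconds(self) -> float:
        return float(
            sum(seg.duration_s for a in self.annotations.values() for seg in a.segments)
        )

    def summary(self) -> dict:
        return {
            "n_subjects": len(self.subjects),
            "n_rounds": self.n_rounds,
            "total_annotated_seconds": self.total_annotated_seconds(),
        }


# ---------------------------------------------------------------------------
# recording CSV


def write_recording(rec: SensorRecording, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# site: {rec.site}\n")
        fh.write(f"# sampling_rate: {rec.sampling_rate:g}\n")
        df = pd.DataFrame(
            {"time_s": rec.t, "gx": rec.gyro[0], "gy": rec.gyro[1], "gz": rec.gyro[2]}
        )
        df.to_csv(fh, index=False, float_format="%.15g")


def read_recording(path: str | Path) -> SensorRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    for col in ("time_s", "gx", "gy", "gz"):
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing column {col!r}")
    return SensorRecording(
        subject_id=meta.get("subject_id", path.stem),
        site=meta.get("site", "wrist"),
        sampling_rate=float(meta.get("sampling_rate", DEFAULT_FS)),
        t=df["time_s"].to_numpy(),
        gyro=np.vstack([df["gx"], df["gy"], df["gz"]]),
    )


# ---------------------------------------------------------------------------
# annotation JSON


def _annotation_to_dict(ann: RoundAnnotation) -> dict:
    return {
        "subject_id": ann.subject_id,
        "round_index": ann.round_index,
        "medication_state": ann.medication_state,
        "segments": [
            {
                "activity": s.activity,
                "start_s": s.start_s,
                "end_s": s.end_s,
                "rater1_mAIMS": s.rater1,
                "rater2_mAIMS": s.rater2,
            }
            for s in ann.segments
        ],
    }


def _annotation_from_dict(d: dict) -> RoundAnnotation:
    segments = [
        Segment(
            activity=s["activity"],
            start_s=float(s["start_s"]),
            end_s=float(s["end_s"]),
            rater1=float(s["rater1_mAIMS"]),
            rater2=float(s["rater2_mAIMS"]),
        )
        for s in d["segments"]
    ]
    return RoundAnnotation(
        subject_id=d["subject_id"],
        round_index=int(d["round_index"]),
        medication_state=d["medication_state"],
        segments=segments,
    )


def write_annotations(annotations: list[RoundAnnotation], path: str | Path) -> None:
    payload = {"rounds": [_annotation_to_dict(a) for a in annotations]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path: str | Path) -> list[RoundAnnotation]:
    payload = json.loads(Path(path).read_text())
    return [_annotation_from_dict(d) for d in payload["rounds"]]


# ---------------------------------------------------------------------------
# assembly


def assemble_dataset(
    recordings: list[SensorRecording], annotations: list[RoundAnnotation]
) -> LabeledDataset:
    """Cross-reference recordings and annotations into a LabeledDataset.

    Every annotation segment must lie within the time support of both of the
    subject's recordings.  Subjects with recordings but no annotations are
    excluded with a warning; annotations without recordings are an error.
    """
    rec_map = {(r.subject_id, r.site): r for r in recordings}
    ann_map: dict[tuple[str, int], RoundAnnotation] = {}
    annotated_subjects = {a.subject_id for a in annotations}
    for ann in annotations:
        for site in SITES:
            rec = rec_map.get((ann.subject_id, site))
            if rec is None:
                raise ValueError(
                    f"annotation for unknown subject {ann.subject_id!r} ({site} recording missing)"
                )
            if ann.segments and (
                ann.start_s < rec.t[0] - 1e-9 or ann.end_s > rec.t[-1] + 1.0 / rec.sampling_rate
            ):
                raise ValueError(
                    f"annotation outside recording support: subject {ann.subject_id} "
                    f"round {ann.round_index} ({site})"
                )
        ann_map[(ann.subject_id, ann.round_index)] = ann
    for (subject, site) in list(rec_map):
        if subject not in annotated_subjects:
            warnings.warn(
                f"recording for subject {subject!r} ({site}) has no annotations; "
                "subject excluded from modeling",
                stacklevel=2,
            )
            del rec_map[(subject, site)]
    return LabeledDataset(recordings=rec_map, annotations=ann_map)


# ---------------------------------------------------------------------------
# cohort directory layout (recordings CSV + annotations JSON + manifest)


def write_cohort(
    recordings: list[SensorRecording],
    annotations: list[RoundAnnotation],
    outdir: str | Path,
    extra_meta: dict | None = None,
) -> Path:
    """Write a cohort to ``outdir`` and return the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec_files = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.site}.csv"
        write_recording(rec, outdir / fname)
        rec_files.append({"subject_id": rec.subject_id, "site": rec.site, "file": fname})
    ann_file = "annotations.json"
    write_annotations(annotations, outdir / ann_file)
    manifest = {
        "subjects": sorted({r.subject_id for r in recordings}),
        "n_rounds": len(annotations),
        "recordings": rec_files,
        "annotations": ann_file,
    }
    if extra_meta:
        manifest.update(extra_meta)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_cohort(indir: str | Path) -> LabeledDataset:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    recordings = [read_recording(indir / e["file"]) for e in manifest["recordings"]]
    annotations = read_annotations(indir / manifest["annotations"])
    return assemble_dataset(recordings, annotations)
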