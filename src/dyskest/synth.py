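"""Seeded synthetic cohort generator.

Emulates the structure of a clinic-visit protocol for levodopa-induced
dyskinesia: each subject wears one gyroscope on the wrist and one on the
ankle of the most affected side and performs rounds of seven activities of
daily living (ADLs), first in the medication OFF state and then, after
taking levodopa, in the ON state.  Dyskinetic movement is simulated as
band-limited 1-4 Hz angular velocity whose RMS grows linearly with the
latent total-mAIMS severity (0-28); walking carries a ~2 Hz fundamental on
the ankle, and OFF rounds add a 4-6 Hz rest-tremor component that is
independent of dyskinesia severity, so that an estimator must learn to
separate tremor from dyskinesia.  Two simulated raters score every activity
trial; their average is the gold standard.

The generator is a study-condition definition, not a biomechanical model:
amplitudes are plausible deg/s scales chosen once and documented, not fits
to real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import MAIMS_MAX, RoundAnnotation, Segment, SensorRecording

ACTIVITIES = (
    "walking",
    "resting",
    "cutting_food",
    "dressing",
    "drinking",
    "unpacking_groceries",
    "combing_hair",
)

# voluntary-movement RMS per activity and site (deg/s); resting is an order
# of magnitude quieter than everything else
_BASE_RMS = {
    "walking": {"wrist": 15.0, "ankle": 60.0},
    "resting": {"wrist": 0.8, "ankle": 0.8},
    "cutting_food": {"wrist": 30.0, "ankle": 2.0},
    "dressing": {"wrist": 35.0, "ankle": 8.0},
    "drinking": {"wrist": 20.0, "ankle": 1.5},
    "unpacking_groceries": {"wrist": 28.0, "ankle": 6.0},
    "combing_hair": {"wrist": 32.0, "ankle": 1.5},
}

# dyskinesia RMS at full-scale severity (mAIMS = 28), per site
_DYSK_FULL_RMS = {"wrist": 45.0, "ankle": 28.0}

# OFF-state rest tremor amplitude scale per site (deg/s)
_TREMOR_RMS = {"wrist": 12.0, "ankle": 5.0}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the clinic protocol the generator emulates: 15 subjects,
    four ~4-min rounds of seven ADLs of 15-60 s each at 64 Hz, with two
    subjects contributing only three rounds (58 rounds in total), dyskinesia
    energy in 1-4 Hz, rest tremor in 4-6 Hz, walking fundamental near 2 Hz,
    and two raters with 1.0-point noise on the 0-28 total-mAIMS scale.
    """

    n_subjects: int = 15
    rounds_per_subject: int = 4
    short_round_subjects: int = 2  # subjects with one round fewer (started ON)
    activities: tuple[str, ...] = ACTIVITIES
    activity_duration_s: tuple[float, float] = (15.0, 60.0)
    sampling_rate: float = 64.0
    dyskinesia_band: tuple[float, float] = (1.0, 4.0)
    tremor_band: tuple[float, float] = (4.0, 6.0)
    walking_fundamental: float = 2.0
    severity_peak_range: tuple[float, float] = (4.0, 24.0)  # per-subject ON peak
    rater_noise_sd: float = 1.0
    inter_round_gap_s: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.rounds_per_subject not in (3, 4):
            raise ValueError("rounds_per_subject must be 3 or 4")
        if not (0 <= self.short_round_subjects <= self.n_subjects):
            raise ValueError("short_round_subjects must be within [0, n_subjects]")
        lo, hi = self.activity_duration_s
        if not (15.0 <= lo <= hi <= 60.0):
            raise ValueError("activity_duration_s must lie within [15, 60]")
        if self.sampling_rate <= 2 * max(self.dyskinesia_band[1], self.tremor_band[1]):
            raise ValueError("sampling_rate must exceed twice the upper band edge")
        if self.rater_noise_sd < 0:
            raise ValueError("rater_noise_sd must be >= 0")
        unknown = [a for a in self.activities if a not in _BASE_RMS]
        if unknown:
            raise ValueError(f"activities contains unknown labels {unknown}; valid: {list(_BASE_RMS)}")


def _band_noise(band: tuple[float, float], n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS random-phase noise band-limited to ``band`` (Hz) via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synth_dyskinesia(
    severity: float,
    duration_s: float,
    rng: np.random.Generator,
    fs: float = 64.0,
    band: tuple[float, float] = (1.0, 4.0),
    site: str = "wrist",
) -> np.ndarray:
    """Additive 3-axis dyskinetic angular velocity for one activity trial.

    Band-limited random-phase noise with total RMS proportional to
    ``severity / 28`` times the site's full-scale amplitude; severity 0
    returns an exactly zero signal.
    """
    if not (0.0 <= severity <= MAIMS_MAX):
        raise ValueError(f"severity {severity} outside [0, {MAIMS_MAX:g}]")
    n = round(duration_s * fs)
    if severity == 0.0:
        return np.zeros((3, n))
    target_rms = (severity / MAIMS_MAX) * _DYSK_FULL_RMS[site]
    # random per-axis energy split so dyskinesia orientation varies by trial
    w = rng.dirichlet(np.ones(3))
    sig = np.vstack([_band_noise(band, n, fs, rng) for _ in range(3)])
    return sig * (target_rms * np.sqrt(3.0 * w))[:, None]


def _tremor(
    duration_s: float,
    rng: np.random.Generator,
    fs: float = 64.0,
    band: tuple[float, float] = (4.0, 6.0),
    site: str = "wrist",
    amp_scale: float = 1.0,
) -> np.ndarray:
    """OFF-state rest tremor: frequency-jittered sinusoid in the 4-6 Hz band."""
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    f0 = rng.uniform(band[0] + 0.3, band[1] - 0.3)
    out = np.zeros((3, n))
    for ax in range(3):
        jitter = np.cumsum(rng.standard_normal(n)) * 0.002
        phase = 2 * np.pi * (f0 * t + jitter) + rng.uniform(0, 2 * np.pi)
        amp = _TREMOR_RMS[site] * amp_scale * rng.uniform(0.5, 1.5)
        out[ax] = amp * np.sqrt(2.0) * np.sin(phase)
    return out


def synth_activity_signal(
    activity: str,
    duration_s: float,
    rng: np.random.Generator,
    site: str = "wrist",
    fs: float = 64.0,
    walking_fundamental: float = 2.0,
) -> np.ndarray:
    """Voluntary-movement component of one activity trial; shape (3, n).

    Walking carries a periodic fundamental near 2 Hz (strongest on the
    ankle, with a first harmonic); resting is near-quiescent; the other
    ADLs are modelled as broadband movement shaped by random burst
    envelopes, mimicking intermittent goal-directed motion.
    """
    if activity not in _BASE_RMS:
        raise ValueError(f"unknown activity {activity!r}; valid labels: {list(_BASE_RMS)}")
    if not (15.0 <= duration_s <= 60.0):
        raise ValueError(f"duration_s {duration_s} outside [15, 60]")
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    rms = _BASE_RMS[activity][site]
    out = np.zeros((3, n))
    if activity == "walking":
        f0 = walking_fundamental * rng.uniform(0.95, 1.05)
        # the gait fundamental dominates the ankle; the wrist mostly carries
        # arm-swing plus broadband movement, so wrist dyskinesia stays legible
        periodic = 1.0 if site == "ankle" else 0.6
        for ax in range(3):
            drift = np.cumsum(rng.standard_normal(n)) * 0.001
            phase = 2 * np.pi * (f0 * t + drift) + rng.uniform(0, 2 * np.pi)
            a1 = periodic * rms * rng.uniform(0.8, 1.2)
            out[ax] = a1 * np.sqrt(2.0) * (np.sin(phase) + 0.3 * np.sin(2 * phase))
        out += (0.1 if site == "ankle" else 0.4) * rms * rng.standard_normal((3, n))
    elif activity == "resting":
        # postural micro-movement: low-amplitude low-frequency noise
        for ax in range(3):
            out[ax] = rms * _band_noise((0.5, 3.0), n, fs, rng)
    else:
        # burst-structured voluntary movement, energy mostly below ~5 Hz
        for ax in range(3):
            carrier = _band_noise((0.5, 5.0), n, fs, rng)
            n_bursts = max(1, int(duration_s / rng.uniform(2.0, 4.0)))
            env = np.full(n, 0.25)
            for _ in range(n_bursts):
                c = rng.uniform(0, duration_s)
                w = rng.uniform(0.5, 2.0)
                env += np.exp(-0.5 * ((t - c) / w) ** 2)
            env /= np.sqrt(np.mean(env**2))
            out[ax] = rms * carrier * env
    return out


def simulate_raters(
    true_severity: float, rng: np.random.Generator, noise_sd: float = 1.0
) -> tuple[float, float, float]:
    """Two raters' integer total-mAIMS scores and their mean (the gold score)."""
    if not (0.0 <= true_severity <= MAIMS_MAX):
        raise ValueError(f"true_severity {true_severity} outside [0, {MAIMS_MAX:g}]")
    scores = []
    for _ in range(2):
        noisy = true_severity + rng.normal(0.0, noise_sd)
        scores.append(float(np.clip(np.round(noisy), 0.0, MAIMS_MAX)))
    r1, r2 = scores
    return r1, r2, (r1 + r2) / 2.0


@dataclass
class _SubjectProfile:
    peak_severity: float          # ON-state dyskinesia peak (total mAIMS)
    off_severity: float           # wearing-off dyskinesia during OFF rounds
    tremor_scale: float           # OFF-state tremor amplitude multiplier
    starts_on: bool               # short-protocol subjects begin in the ON state
    n_rounds: int
    round_severity: list = field(default_factory=list)
    round_state: list = field(default_factory=list)


def _make_profile(cfg: CohortConfig, starts_on: bool, rng: np.random.Generator) -> _SubjectProfile:
    peak = rng.uniform(*cfg.severity_peak_range)
    off = peak * rng.uniform(0.0, 0.15)  # low-but-possibly-nonzero wearing-off dyskinesia
    n_rounds = cfg.rounds_per_subject - (1 if starts_on else 0)
    prof = _SubjectProfile(
        peak_severity=peak,
        off_severity=off,
        tremor_scale=rng.uniform(0.5, 1.5),
        starts_on=starts_on,
        n_rounds=n_rounds,
    )
    for r in range(n_rounds):
        state = "ON" if (starts_on or r > 0) else "OFF"
        if state == "OFF":
            sev = off
        else:
            # severity peaks shortly after the dose then decays over later rounds
            decay = 1.0 if r <= 1 else rng.uniform(0.6, 0.95)
            sev = peak * decay
        prof.round_severity.append(float(np.clip(sev, 0.0, MAIMS_MAX)))
        prof.round_state.append(state)
    return prof


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[SensorRecording], list[RoundAnnotation]]:
    """Generate a full synthetic cohort; deterministic given ``config.seed``.

    Returns one wrist and one ankle recording per subject (a single
    continuous stream covering all of that subject's rounds, separated by
    short quiescent gaps) plus one annotation per round.
    """
    cfg = config if config is not None else CohortConfig()
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    fs = cfg.sampling_rate
    recordings: list[SensorRecording] = []
    annotations: list[RoundAnnotation] = []

    subject_seeds = master.spawn(cfg.n_subjects)
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        subject_id = f"S{i + 1:02d}"
        starts_on = i < cfg.short_round_subjects
        prof = _make_profile(cfg, starts_on, rng)

        streams = {site: [] for site in ("wrist", "ankle")}
        cursor = 0.0
        for r in range(prof.n_rounds):
            state = prof.round_state[r]
            round_sev = prof.round_severity[r]
            segments: list[Segment] = []
            for activity in cfg.activities:
                dur = float(rng.uniform(*cfg.activity_duration_s))
                n = round(dur * fs)
                dur = n / fs  # snap to the sample grid
                # per-activity severity wobbles mildly around the round level
                sev = float(np.clip(round_sev + rng.normal(0.0, 0.5), 0.0, MAIMS_MAX))
                if round_sev == 0.0:
                    sev = 0.0
                # identical per-site child streams must be generated in a fixed
                # order for determinism
                for site in ("wrist", "ankle"):
                    sig = synth_activity_signal(
                        activity, dur, rng, site=site, fs=fs,
                        walking_fundamental=cfg.walking_fundamental,
                    )
                    sig = sig + synth_dyskinesia(
                        sev, dur, rng, fs=fs, band=cfg.dyskinesia_band, site=site
                    )
                    if state == "OFF":
                        sig = sig + _tremor(
                            dur, rng, fs=fs, band=cfg.tremor_band, site=site,
                            amp_scale=prof.tremor_scale,
                        )
                    streams[site].append(sig)
                r1, r2, _ = simulate_raters(sev, rng, cfg.rater_noise_sd)
                segments.append(
                    Segment(activity=activity, start_s=cursor, end_s=cursor + dur,
                            rater1=r1, rater2=r2)
                )
                cursor += dur
            annotations.append(
                RoundAnnotation(
                    subject_id=subject_id,
                    round_index=r + 1,
                    medication_state=state,
                    segments=segments,
                )
            )
            if r < prof.n_rounds - 1:
                gap_n = round(cfg.inter_round_gap_s * fs)
                for site in ("wrist", "ankle"):
                    streams[site].append(0.5 * rng.standard_normal((3, gap_n)))
                cursor += gap_n / fs

        for site in ("wrist", "ankle"):
            gyro = np.concatenate(streams[site], axis=1)
            t = np.arange(gyro.shape[1]) / fs
            recordings.append(
                SensorRecording(
                    subject_id=subject_id, site=site, sampling_rate=fs, t=t, gyro=gyro
                )
            )
    return recordings, annotations


def small_cohort_config(seed: int = 0) -> CohortConfig:
    """A reduced cohort for quick experiments: 6 subjects, 2 rounds, short trials."""
    return CohortConfig(
        n_subjects=6,
        rounds_per_subject=3,
        short_round_subjects=0,
        activity_duration_s=(15.0, 20.0),
        seed=seed,
    )


def with_seed(cfg: CohortConfig, seed: int) -> CohortConfig:
    return replace(cfg, seed=seed)
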