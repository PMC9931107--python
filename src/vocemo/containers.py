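"""In-memory containers for audio, contours and per-utterance features."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .emotions import EmotionLabel

#: Speech-material categories a stimulus can belong to.
SPEECH_TYPES = ("spontaneous", "acting_words", "acting_phrases", "meaningless_text")


@dataclass
class Utterance:
    """A mono waveform with its stimulus metadata.

    ``samples`` are float amplitudes in [-1, 1]; duration is implied by
    ``len(samples) / sample_rate``.
    """

    samples: np.ndarray
    sample_rate: int
    emotion: EmotionLabel | None = None
    language: str = ""
    speech_type: str = "spontaneous"
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("utterance must hold a non-empty 1-D sample array")
        peak = float(np.max(np.abs(self.samples)))
        if not np.isfinite(peak) or peak > 1.0 + 1e-6:
            raise ValueError(f"amplitudes must be finite and within [-1, 1]; peak={peak}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.emotion is not None:
            self.emotion = EmotionLabel.from_string(self.emotion)
        if self.speech_type not in SPEECH_TYPES:
            raise ValueError(f"speech_type must be one of {SPEECH_TYPES}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate


@dataclass
class F0Contour:
    """Per-frame fundamental-frequency track; NaN marks unvoiced frames."""

    frame_times: np.ndarray  # seconds, frame centers
    f0: np.ndarray           # Hz; NaN where unvoiced
    frame_hop_ms: float

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        self.f0 = np.asarray(self.f0, dtype=np.float64)
        if self.frame_times.shape != self.f0.shape:
            raise ValueError("frame_times and f0 must have the same length")

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())


@dataclass
class EnergyContour:
    """Per-frame RMS energy in dB re full-scale RMS 1.0."""

    frame_times: np.ndarray
    e_db: np.ndarray
    frame_hop_ms: float

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        self.e_db = np.asarray(self.e_db, dtype=np.float64)
        if self.frame_times.shape != self.e_db.shape:
            raise ValueError("frame_times and e_db must have the same length")


@dataclass
class AcousticFeatures:
    """The per-utterance prosodic feature vector.

    F0 statistics are over voiced frames only.  The energy ratios are
    linear-power ratios derived from dB differences, 10**((Ea - Eb)/10);
    the underlying dB differences are carried alongside. E0max and E0min
    are the frame energies at the frames of F0max and F0min respectively,
    not global energy extrema.
    """

    duration_ms: float
    f0_mean: float
    f0_max: float
    f0_min: float
    f0_range: float
    e0_mean: float
    emax_over_e0: float
    e0min_over_e0: float
    emax_over_emin: float
    emax_minus_e0_db: float = field(default=np.nan)
    e0min_minus_e0_db: float = field(default=np.nan)
    emax_minus_emin_db: float = field(default=np.nan)
    id: str = ""

    def __post_init__(self) -> None:
        if not (self.f0_min - 1e-9 <= self.f0_mean <= self.f0_max + 1e-9):
            raise ValueError("f0 statistics must satisfy f0_min <= f0_mean <= f0_max")
        if abs(self.f0_range - (self.f0_max - self.f0_min)) > 1e-9:
            raise ValueError("f0_range must equal f0_max - f0_min")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")

    FIELDS = (
        "duration_ms", "f0_mean", "f0_max", "f0_min", "f0_range", "e0_mean",
        "emax_over_e0", "e0min_over_e0", "emax_over_emin",
        "emax_minus_e0_db", "e0min_minus_e0_db", "emax_minus_emin_db",
    )

    def as_dict(self) -> dict:
        d = asdict(self)
        return {"id": d.pop("id"), **d}
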