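"""Seeded synthetic emotional utterances.

The generator is deliberately minimal: a 6-harmonic additive source with
1/k amplitude roll-off, a single raised-cosine F0 excursion over a base
pitch, a raised-cosine amplitude envelope whose depth (``energy_tilt_db``)
shapes the Emax/E0 and E0min/E0 ratios, and additive Gaussian noise at a
configurable SNR.  It makes no attempt at naturalistic speech — no formants,
no phonemes — but its F0 and energy structure is exactly recoverable by the
trackers in :mod:`vocemo.acoustics`, which is what makes the downstream
statistics testable.

Default presets encode the qualitative emotion contrasts reported for
emotional child speech: joy has the widest F0 excursion and the longest
duration, anger the shortest duration, sadness the lowest base pitch, and
neutral the flattest energy envelope.  A per-language F0 offset emulates a
higher-pitched speaker group.  The absolute Hz/ms values are configuration,
not claims about any real corpus.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .acoustics import write_wav
from .containers import F0Contour, Utterance
from .emotions import EMOTIONS, EmotionLabel
from .errors import AliasingError, InvalidSpecError

N_HARMONICS = 6

LANGUAGES = ("lang_A", "lang_B")


@dataclass(frozen=True)
class EmotionPreset:
    """Acoustic target for one emotion category.

    f0_excursion is the peak-to-trough span of the raised-cosine contour,
    so the noiseless contour has max - min = f0_excursion and mean = f0_mean.
    energy_tilt_db is the envelope depth from the mid-utterance maximum to
    the edges.  jitter_sd_hz adds frame-level Gaussian pitch noise.
    """

    emotion: EmotionLabel
    f0_mean: float
    f0_excursion: float
    duration_mean_ms: float
    duration_sd_ms: float
    energy_tilt_db: float
    jitter_sd_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "emotion", EmotionLabel.from_string(self.emotion))
        if self.f0_mean <= 0:
            raise InvalidSpecError("f0_mean must be positive")
        if self.f0_excursion < 0 or self.f0_mean - self.f0_excursion <= 50.0:
            raise InvalidSpecError("need f0_mean - f0_excursion > 50 Hz")
        if self.duration_mean_ms <= 0 or self.duration_sd_ms < 0:
            raise InvalidSpecError("durations must be positive")
        if self.jitter_sd_hz < 0:
            raise InvalidSpecError("jitter_sd_hz must be non-negative")


def default_presets() -> dict[EmotionLabel, EmotionPreset]:
    """The default four-emotion preset bank.

    Orderings encoded: joy has the largest f0_excursion and the longest
    duration; anger the shortest duration; sadness the lowest f0_mean;
    neutral the smallest energy tilt.
    """
    bank = [
        EmotionPreset(EmotionLabel.JOY, f0_mean=280.0, f0_excursion=140.0,
                      duration_mean_ms=900.0, duration_sd_ms=80.0,
                      energy_tilt_db=8.0, jitter_sd_hz=3.0),
        EmotionPreset(EmotionLabel.NEUTRAL, f0_mean=240.0, f0_excursion=60.0,
                      duration_mean_ms=800.0, duration_sd_ms=80.0,
                      energy_tilt_db=2.0, jitter_sd_hz=2.0),
        EmotionPreset(EmotionLabel.SADNESS, f0_mean=210.0, f0_excursion=40.0,
                      duration_mean_ms=800.0, duration_sd_ms=80.0,
                      energy_tilt_db=4.0, jitter_sd_hz=2.0),
        EmotionPreset(EmotionLabel.ANGER, f0_mean=260.0, f0_excursion=110.0,
                      duration_mean_ms=450.0, duration_sd_ms=50.0,
                      energy_tilt_db=10.0, jitter_sd_hz=3.0),
    ]
    return {p.emotion: p for p in bank}


@dataclass(frozen=True)
class CorpusSpec:
    """Design of one synthetic corpus (one language group)."""

    n_per_emotion: int = 30
    language: str = "lang_A"
    language_f0_offset: float = 40.0  # Hz added to f0_mean for lang_B
    sample_rate: int = 16000
    noise_snr: float = 30.0  # dB; np.inf = noiseless
    seed: int = 0
    speech_type: str = "spontaneous"
    frame_hop_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.n_per_emotion < 1:
            raise InvalidSpecError("n_per_emotion must be >= 1")
        if self.language not in LANGUAGES:
            raise InvalidSpecError(f"language must be one of {LANGUAGES}")
        if self.sample_rate not in (16000, 44100):
            raise InvalidSpecError("sample_rate must be 16000 or 44100 Hz")
        if self.noise_snr < 0:
            raise InvalidSpecError("noise_snr must be >= 0 dB")


def make_f0_contour(
    preset: EmotionPreset,
    duration_ms: float,
    frame_hop_ms: float = 10.0,
    rng_seed: int = 0,
) -> F0Contour:
    """Target F0 contour: raised-cosine excursion plus frame-level jitter.

    The noiseless contour starts and ends at ``f0_mean - excursion/2``,
    peaks at ``f0_mean + excursion/2`` mid-utterance, and averages exactly
    ``f0_mean`` over the frame grid.
    """
    if duration_ms <= 2 * frame_hop_ms:
        raise InvalidSpecError("duration must exceed two frame hops")
    n = int(round(duration_ms / frame_hop_ms))
    k = np.arange(n)
    base = preset.f0_mean - preset.f0_excursion / 2.0
    f0 = base + preset.f0_excursion * 0.5 * (1.0 - np.cos(2.0 * np.pi * k / n))
    if preset.jitter_sd_hz > 0:
        rng = np.random.default_rng(rng_seed)
        f0 = f0 + rng.normal(0.0, preset.jitter_sd_hz, size=n)
    times = k * frame_hop_ms / 1000.0
    return F0Contour(frame_times=times, f0=f0, frame_hop_ms=frame_hop_ms)


def synthesize_utterance(
    contour: F0Contour,
    preset: EmotionPreset,
    spec: CorpusSpec,
    rng_seed: int = 0,
    utt_id: str = "",
    envelope: np.ndarray | None = None,
) -> Utterance:
    """Render a contour as a 6-harmonic waveform.

    Per-sample frequency is interpolated from the frame contour and
    integrated into a continuous phase, so the tracked pitch of the output
    recovers the contour.  ``envelope`` overrides the default raised-cosine
    amplitude envelope (linear amplitude per sample); an all-zero envelope
    yields a silent (all-unvoiced) utterance, never NaN samples.
    """
    if contour.f0.size == 0:
        raise InvalidSpecError("contour is empty")
    sr = spec.sample_rate
    nyq = sr / 2.0
    if np.nanmax(contour.f0) * N_HARMONICS >= nyq:
        raise AliasingError(
            f"contour F0 up to {np.nanmax(contour.f0):.0f} Hz needs harmonics above "
            f"Nyquist ({nyq:.0f} Hz) at {N_HARMONICS} harmonics"
        )
    duration_s = contour.f0.size * contour.frame_hop_ms / 1000.0
    n_samples = int(round(duration_s * sr))
    t = np.arange(n_samples) / sr
    f0_inst = np.interp(t, contour.frame_times, contour.f0)
    phase = 2.0 * np.pi * np.cumsum(f0_inst) / sr
    signal = np.zeros(n_samples)
    for k in range(1, N_HARMONICS + 1):
        signal += np.sin(k * phase) / k

    if envelope is None:
        # raised-cosine in dB: 0 dB mid-utterance (where F0 peaks), -tilt at edges
        env_db = -preset.energy_tilt_db * 0.5 * (1.0 + np.cos(2.0 * np.pi * t / duration_s))
        envelope = 10.0 ** (env_db / 20.0)
    else:
        envelope = np.asarray(envelope, dtype=np.float64)
        if envelope.size != n_samples:
            envelope = np.interp(t, np.linspace(0, duration_s, envelope.size), envelope)
    x = signal * envelope

    rms = float(np.sqrt(np.mean(x * x)))
    if rms > 0 and np.isfinite(spec.noise_snr):
        rng = np.random.default_rng(rng_seed)
        noise_sd = rms * 10.0 ** (-spec.noise_snr / 20.0)
        x = x + rng.normal(0.0, noise_sd, size=n_samples)

    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = x * (0.9 / peak)
    return Utterance(
        samples=x, sample_rate=sr, emotion=preset.emotion,
        language=spec.language, speech_type=spec.speech_type, id=utt_id,
    )


def generate_corpus(
    spec: CorpusSpec,
    presets: dict[EmotionLabel, EmotionPreset] | list[EmotionPreset] | None = None,
    out_dir: str | Path | None = None,
) -> list[Utterance]:
    """Generate ``n_per_emotion`` utterances per emotion, deterministically.

    With ``out_dir`` set, writes one 16-bit PCM WAV per utterance plus a
    ``manifest.csv`` (id, path, language, emotion, speech_type, duration_ms,
    seed).  The same (spec, presets) pair always yields byte-identical audio.
    """
    if presets is None:
        presets = default_presets()
    if isinstance(presets, list):
        bank: dict[EmotionLabel, EmotionPreset] = {}
        for p in presets:
            if p.emotion in bank:
                raise InvalidSpecError(f"duplicate preset for emotion {p.emotion.value}")
            bank[p.emotion] = p
        presets = bank
    missing = [e.value for e in EMOTIONS if e not in presets]
    if missing:
        raise InvalidSpecError(f"missing preset for emotions: {missing}")

    if spec.language == "lang_B" and spec.language_f0_offset:
        presets = {
            e: replace(p, f0_mean=p.f0_mean + spec.language_f0_offset)
            for e, p in presets.items()
        }

    master = np.random.default_rng(spec.seed)
    utterances: list[Utterance] = []
    manifest_rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for emotion in EMOTIONS:
        preset = presets[emotion]
        for i in range(spec.n_per_emotion):
            dur_seed, contour_seed, noise_seed = master.integers(0, 2**31 - 1, size=3)
            dur_rng = np.random.default_rng(dur_seed)
            duration = float(dur_rng.normal(preset.duration_mean_ms, preset.duration_sd_ms))
            duration = max(duration, 4 * spec.frame_hop_ms + 1.0, 200.0)
            utt_id = f"{spec.language}_{emotion.value}_{i:03d}"
            contour = make_f0_contour(preset, duration, spec.frame_hop_ms, int(contour_seed))
            utt = synthesize_utterance(contour, preset, spec, int(noise_seed), utt_id)
            utterances.append(utt)
            if out_path is not None:
                wav_path = out_path / f"{utt_id}.wav"
                write_wav(wav_path, utt)
                manifest_rows.append({
                    "id": utt_id, "path": wav_path.name,
                    "language": spec.language, "emotion": emotion.value,
                    "speech_type": spec.speech_type,
                    "duration_ms": f"{utt.duration_ms:.3f}", "seed": spec.seed,
                })

    if out_path is not None:
        with open(out_path / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(manifest_rows[0].keys()))
            writer.writeheader()
            writer.writerows(manifest_rows)
    return utterances
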