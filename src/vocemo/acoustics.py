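"""Prosodic feature extraction from WAV audio.

The feature set is the classic emotional-prosody vector: utterance duration,
F0 statistics (mean, max, min, range over voiced frames) and frame-energy
ratios in dB.  Pitch is tracked with a normalized-autocorrelation estimator:
Hann-windowed 40 ms frames at a 10 ms hop, candidate peaks searched in the
100-600 Hz lag window (child voices), parabolic interpolation around the
winning lag, a voicing threshold on the normalized peak value, and a running
median to suppress octave errors.  All of these settings are exposed as
:class:`TrackingParams` and in the YAML config.

Energy ratios follow the linear-power convention: for two frame levels in dB
the ratio is ``10**((Ea - Eb)/10)``; quotients of raw dB values would depend
on the dB reference and are not physical quantities.  E0max / E0min are the
energies at the frames where F0 attains its max / min.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .containers import AcousticFeatures, EnergyContour, F0Contour, Utterance
from .errors import FeatureExtractionError, UnsupportedFormatError

DB_FLOOR = -120.0  # dB value assigned to silent frames


@dataclass
class TrackingParams:
    """Frame-analysis settings for the pitch and energy trackers."""

    frame_ms: float = 40.0
    hop_ms: float = 10.0
    f0_search: tuple[float, float] = (100.0, 600.0)
    voicing_threshold: float = 0.30
    median_width: int = 5
    trim_silence: bool = False
    trim_threshold_db: float = -50.0

    def __post_init__(self) -> None:
        lo, hi = self.f0_search
        if not (0 < lo < hi):
            raise ValueError("f0 search range must satisfy 0 < lo < hi")
        if self.median_width < 1 or self.median_width % 2 == 0:
            raise ValueError("median_width must be an odd positive integer")


# ---------------------------------------------------------------------------
# WAV I/O

def read_wav(path: str | Path, **metadata) -> Utterance:
    """Read a RIFF PCM WAV file into an :class:`Utterance`.

    Both recording dialects are accepted (16 kHz and 44.1 kHz, 16-bit PCM);
    stereo input is down-mixed to mono with a warning.  Samples are scaled
    to float in [-1, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise UnsupportedFormatError(f"{path}: empty file")
    try:
        sr, data = wavfile.read(str(path))
    except ValueError as exc:
        raise UnsupportedFormatError(f"{path}: not a readable RIFF/PCM WAV ({exc})") from exc
    if data.size == 0:
        raise UnsupportedFormatError(f"{path}: zero-length audio stream")
    if data.ndim == 2:
        warnings.warn(f"{path.name}: stereo input down-mixed to mono", stacklevel=2)
        data = data.astype(np.float64).mean(axis=1)
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float PCM or already down-mixed
        samples = np.asarray(data, dtype=np.float64)
    samples = np.clip(samples, -1.0, 1.0)
    metadata.setdefault("id", path.stem)
    return Utterance(samples=samples, sample_rate=int(sr), **metadata)


def write_wav(path: str | Path, utt: Utterance) -> None:
    """Write an utterance as mono 16-bit PCM RIFF WAV."""
    x = np.clip(utt.samples, -1.0, 1.0)
    wavfile.write(str(path), utt.sample_rate, np.round(x * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# frame-level estimation

def estimate_f0_frame(
    frame: np.ndarray,
    sample_rate: int,
    search: tuple[float, float] = (100.0, 600.0),
    voicing_threshold: float = 0.30,
) -> float:
    """Estimate F0 of one frame by normalized autocorrelation.

    Returns the interpolated F0 in Hz, or NaN if the frame is judged
    unvoiced (normalized peak below the voicing threshold, or degenerate).
    Among near-maximal autocorrelation peaks the shortest lag wins, which
    suppresses octave-down errors on harmonic-rich frames.
    """
    x = np.asarray(frame, dtype=np.float64)
    n = x.size
    f0_lo, f0_hi = search
    lag_min = int(np.floor(sample_rate / f0_hi))
    lag_max = int(np.ceil(sample_rate / f0_lo))
    if lag_max >= n or lag_min < 2:
        return np.nan
    x = x - x.mean()
    if not np.any(x):
        return np.nan
    w = np.hanning(n)
    xw = x * w

    # lag-normalized ACF: the windowed signal's ACF divided by the window's
    # own ACF, which removes the taper-induced tilt so a periodic frame
    # peaks at exactly 1 at its period
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    ac = np.fft.irfft(np.abs(np.fft.rfft(xw, nfft)) ** 2, nfft)[: lag_max + 2]
    acw = np.fft.irfft(np.abs(np.fft.rfft(w, nfft)) ** 2, nfft)[: lag_max + 2]
    if ac[0] <= 0:
        return np.nan
    r = (ac / ac[0]) / (acw / acw[0])

    window = r[lag_min : lag_max + 1]
    if window.size < 3:
        return np.nan
    rmax = float(np.max(window))
    if rmax < voicing_threshold:
        return np.nan
    # local maxima within 2% (abs 0.02) of the global peak; shortest lag wins
    interior = window[1:-1]
    is_peak = (interior >= window[:-2]) & (interior >= window[2:])
    near = interior >= max(rmax - 0.02, 0.97 * rmax)
    cand = np.flatnonzero(is_peak & near)
    if cand.size == 0:
        lag = lag_min + int(np.argmax(window))
    else:
        lag = lag_min + 1 + int(cand[0])
    # parabolic interpolation around the winning lag
    if 1 <= lag < lag_max + 1:
        ym1, y0, yp1 = r[lag - 1], r[lag], r[lag + 1]
        denom_p = ym1 - 2 * y0 + yp1
        delta = 0.0 if abs(denom_p) < 1e-12 else 0.5 * (ym1 - yp1) / denom_p
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f0 = sample_rate / (lag + delta)
    if not (f0_lo * 0.9 <= f0 <= f0_hi * 1.1):
        return np.nan
    return float(f0)


def _frame_starts(n_samples: int, frame_len: int, hop: int) -> np.ndarray:
    if n_samples < frame_len:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - frame_len + 1, hop)


def _running_median(values: np.ndarray, width: int) -> np.ndarray:
    """Running median over voiced (finite) entries; NaNs pass through."""
    if width <= 1:
        return values.copy()
    out = values.copy()
    half = width // 2
    voiced_idx = np.flatnonzero(np.isfinite(values))
    m = voiced_idx.size
    for j, i in enumerate(voiced_idx):
        # window shrinks symmetrically near the ends to avoid edge bias
        h = min(half, j, m - 1 - j)
        neighborhood = values[voiced_idx[j - h : j + h + 1]]
        out[i] = np.median(neighborhood)
    return out


def track_f0(utt: Utterance, params: TrackingParams | None = None) -> F0Contour:
    """Track F0 over the utterance; unvoiced frames are NaN.

    Per-frame autocorrelation estimates are post-processed with a running
    median over voiced frames (octave-error suppression).
    """
    params = params or TrackingParams()
    frame_len = int(round(params.frame_ms * utt.sample_rate / 1000.0))
    hop = int(round(params.hop_ms * utt.sample_rate / 1000.0))
    starts = _frame_starts(utt.samples.size, frame_len, hop)
    if starts.size < 2:
        raise FeatureExtractionError(
            f"utterance {utt.id!r} too short for frame analysis "
            f"({utt.duration_ms:.1f} ms < 2 frames)"
        )
    f0 = np.array([
        estimate_f0_frame(
            utt.samples[s : s + frame_len], utt.sample_rate,
            params.f0_search, params.voicing_threshold,
        )
        for s in starts
    ])
    f0 = _running_median(f0, params.median_width)
    times = (starts + frame_len / 2) / utt.sample_rate
    return F0Contour(frame_times=times, f0=f0, frame_hop_ms=params.hop_ms)


def track_energy(utt: Utterance, params: TrackingParams | None = None) -> EnergyContour:
    """Frame RMS energy in dB re full-scale RMS 1.0; silent frames floor at -120 dB."""
    params = params or TrackingParams()
    frame_len = int(round(params.frame_ms * utt.sample_rate / 1000.0))
    hop = int(round(params.hop_ms * utt.sample_rate / 1000.0))
    starts = _frame_starts(utt.samples.size, frame_len, hop)
    if starts.size < 2:
        raise FeatureExtractionError(
            f"utterance {utt.id!r} too short for frame analysis"
        )
    idx = starts[:, None] + np.arange(frame_len)[None, :]
    frames = utt.samples[idx]
    rms = np.sqrt(np.mean(frames * frames, axis=1))
    with np.errstate(divide="ignore"):
        e_db = 20.0 * np.log10(rms)
    e_db = np.maximum(e_db, DB_FLOOR)
    times = (starts + frame_len / 2) / utt.sample_rate
    return EnergyContour(frame_times=times, e_db=e_db, frame_hop_ms=params.hop_ms)


# ---------------------------------------------------------------------------
# feature extraction

def _trim_span(e_db: np.ndarray, threshold_db: float) -> slice:
    above = np.flatnonzero(e_db > threshold_db)
    if above.size == 0:
        return slice(0, e_db.size)
    return slice(above[0], above[-1] + 1)


def extract_features(utt: Utterance, params: TrackingParams | None = None) -> AcousticFeatures:
    """Compute the per-utterance feature vector.

    F0 statistics use voiced frames only; E0 is the mean frame level (dB)
    over voiced frames.  Raises :class:`FeatureExtractionError` when no
    frame is voiced.
    """
    params = params or TrackingParams()
    contour = track_f0(utt, params)
    energy = track_energy(utt, params)
    voiced = contour.voiced
    if params.trim_silence:
        span = _trim_span(energy.e_db, params.trim_threshold_db)
        keep = np.zeros_like(voiced)
        keep[span] = True
        voiced = voiced & keep
        n = min(contour.f0.size, energy.e_db.size)
        duration_ms = (span.stop - span.start) * params.hop_ms
    else:
        duration_ms = utt.duration_ms
    if not np.any(voiced):
        raise FeatureExtractionError(f"utterance {utt.id!r}: no voiced frames")

    n = min(contour.f0.size, energy.e_db.size)
    f0 = contour.f0[:n]
    e_db = energy.e_db[:n]
    voiced = voiced[:n]
    vf0 = f0[voiced]
    ve = e_db[voiced]

    f0_mean = float(np.mean(vf0))
    i_max = int(np.argmax(vf0))
    i_min = int(np.argmin(vf0))
    f0_max = float(vf0[i_max])
    f0_min = float(vf0[i_min])
    e0 = float(np.mean(ve))
    emax_db = float(ve[i_max])  # energy at the F0max frame
    emin_db = float(ve[i_min])  # energy at the F0min frame

    def power_ratio(da: float, db_: float) -> float:
        return float(10.0 ** ((da - db_) / 10.0))

    return AcousticFeatures(
        duration_ms=float(duration_ms),
        f0_mean=f0_mean,
        f0_max=f0_max,
        f0_min=f0_min,
        f0_range=f0_max - f0_min,
        e0_mean=e0,
        emax_over_e0=power_ratio(emax_db, e0),
        e0min_over_e0=power_ratio(emin_db, e0),
        emax_over_emin=power_ratio(emax_db, emin_db),
        emax_minus_e0_db=emax_db - e0,
        e0min_minus_e0_db=emin_db - e0,
        emax_minus_emin_db=emax_db - emin_db,
        id=utt.id,
    )


def features_table(
    utterances: list[Utterance], params: TrackingParams | None = None
) -> pd.DataFrame:
    """Extract features for a corpus into a tidy DataFrame (one row per utterance)."""
    rows = []
    for utt in utterances:
        feats = extract_features(utt, params)
        row = feats.as_dict()
        row["emotion"] = utt.emotion.value if utt.emotion else ""
        row["language"] = utt.language
        row["speech_type"] = utt.speech_type
        rows.append(row)
    return pd.DataFrame(rows)
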