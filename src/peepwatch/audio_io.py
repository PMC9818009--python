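"""Audio I/O and windowing.

Recordings are mono waveforms with samples in [-1, 1]. The analysis
convention is a 51.2 kHz sampling rate and fixed half-minute analysis
windows; both are parameters, not assumptions baked into the feature code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: reference sampling rate of the recording chain (Hz)
DEFAULT_RATE = 51_200

#: default analysis window length (s)
DEFAULT_WINDOW_S = 30.0


class AudioFormatError(ValueError):
    """Raised when a file is not a readable mono/stereo PCM WAV."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal.

    Attributes
    ----------
    samples : np.ndarray
        1-D float array; after normalization all values lie in [-1, 1].
    sampling_rate : float
        Samples per second, > 0.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds (= n_samples / sampling_rate)."""
        return len(self.samples) / self.sampling_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class AnalysisWindow:
    """One contiguous, half-open [start, start+length) analysis slice."""

    recording_id: str
    start: float
    length: float
    waveform: Waveform = field(repr=False)


def read_audio(path: str | Path, normalize: bool = False) -> Waveform:
    """Read a PCM WAV file as a mono :class:`Waveform`.

    Multi-channel files are averaged to mono. With ``normalize=True`` the
    result is peak-normalized into [-1, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    if path.stat().st_size == 0:
        raise AudioFormatError(f"empty audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise AudioFormatError(f"unreadable WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"audio file contains no samples: {path}")

    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:  # channels in columns -> average to mono
        samples = samples.mean(axis=1)
    if normalize:
        peak = np.max(np.abs(samples))
        if peak > 0:
            samples = samples / peak
    return Waveform(samples, float(rate))


def write_audio(path: str | Path, w: Waveform, subtype: str = "PCM_16") -> None:
    """Write a mono WAV file, 16-bit PCM (default) or 32-bit float."""
    path = Path(path)
    x = np.clip(w.samples, -1.0, 1.0)
    if subtype == "PCM_16":
        wavfile.write(path, int(round(w.sampling_rate)), np.round(x * 32767).astype(np.int16))
    elif subtype in ("FLOAT", "float32"):
        wavfile.write(path, int(round(w.sampling_rate)), x.astype(np.float32))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}; use 'PCM_16' or 'float32'")


def resample(w: Waveform, target_rate: float = DEFAULT_RATE) -> Waveform:
    """Polyphase-resample to ``target_rate`` (off the default path; features
    carry the actual rate)."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == w.sampling_rate:
        return w
    from fractions import Fraction

    frac = Fraction(int(round(target_rate)), int(round(w.sampling_rate))).limit_denominator(1000)
    samples = resample_poly(w.samples, frac.numerator, frac.denominator)
    return Waveform(np.asarray(samples), float(target_rate))


def segment_windows(
    w: Waveform,
    window_s: float = DEFAULT_WINDOW_S,
    recording_id: str = "",
) -> list[AnalysisWindow]:
    """Cut a recording into contiguous non-overlapping analysis windows.

    Returns ``floor(duration / window_s)`` full windows; a trailing partial
    window is dropped (energy features are duration-sensitive) and logged.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    samples_per = int(round(window_s * w.sampling_rate))
    n_full = len(w) // samples_per
    tail = len(w) - n_full * samples_per
    if tail:
        logger.warning(
            "dropping %.3f s partial trailing window of %s",
            tail / w.sampling_rate,
            recording_id or "recording",
        )
    windows = []
    for i in range(n_full):
        sl = w.samples[i * samples_per : (i + 1) * samples_per]
        windows.append(
            AnalysisWindow(
                recording_id=recording_id,
                start=i * window_s,
                length=window_s,
                waveform=Waveform(sl, w.sampling_rate),
            )
        )
    return windows
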