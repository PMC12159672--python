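"""Audio I/O and spectral primitives.

Everything downstream (acoustic indices, rain screening, the synthetic
soundscape) consumes the containers defined here: :class:`AudioClip`
(waveform normalized to [-1, 1]) and :class:`Spectrogram` (magnitude STFT).

Conventions, fixed and documented:

* STFT window: periodic Hann; default length 512 samples, no overlap.
* Spectrogram rows: ``window_length // 2 + 1`` (rfft bins, Nyquist included).
* Band-pass filtering: FFT-domain masking (linear phase, brick-wall).
* WAV files: PCM 16-bit mono; filenames ``<site>_<YYYYMMDD>_<HHMMSS>.wav``
  carry site and timestamp metadata.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, hilbert

__all__ = [
    "AudioClip",
    "Spectrogram",
    "MeanSpectrum",
    "read_wav",
    "write_wav",
    "parse_clip_filename",
    "compute_spectrogram",
    "bandpass_filter",
    "mean_spectrum",
    "amplitude_envelope",
]

_FULL_SCALE = 32768.0  # int16 negative full scale; positive max is 32767

_FILENAME_RE = re.compile(
    r"^(?P<site>.+)_(?P<date>\d{8})_(?P<time>\d{6})$"
)


@dataclass
class AudioClip:
    """A mono recording with samples normalized to [-1, 1]."""

    samples: np.ndarray
    sample_rate: float
    clip_id: str = ""
    site: str = ""
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        peak = np.max(np.abs(self.samples))
        if peak > 1.0 + 1e-9:
            raise ValueError(f"samples exceed full scale (peak {peak:.4g})")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "AudioClip":
        return replace(self, samples=samples)


@dataclass
class Spectrogram:
    """Magnitude STFT: nonnegative (frequency bins x time frames) matrix."""

    amplitude: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    window_length: int
    overlap: float = 0.0

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if np.any(self.amplitude < 0):
            raise ValueError("spectrogram amplitudes must be nonnegative")
        if np.any(np.diff(self.freq_axis) <= 0):
            raise ValueError("freq_axis must be strictly ascending")

    @property
    def n_bins(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_frames(self) -> int:
        return self.amplitude.shape[1]

    def band(self, f_min: float, f_max: float) -> np.ndarray:
        """Boolean row mask for bins with f_min <= f <= f_max."""
        return (self.freq_axis >= f_min) & (self.freq_axis <= f_max)


@dataclass
class MeanSpectrum:
    """Time-averaged amplitude spectrum, normalized so the maximum is 1."""

    freq_axis: np.ndarray
    amplitude: np.ndarray
    silent: bool = False


def parse_clip_filename(name: str) -> tuple[str, datetime] | None:
    """Parse ``<site>_<YYYYMMDD>_<HHMMSS>`` from a filename stem."""
    m = _FILENAME_RE.match(Path(name).stem)
    if m is None:
        return None
    try:
        ts = datetime.strptime(m.group("date") + m.group("time"), "%Y%m%d%H%M%S")
    except ValueError:
        return None
    return m.group("site"), ts


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip`.

    Integer samples are scaled to [-1, 1] by the type's full scale. Multi
    channel input keeps channel 1 with a warning. Site and timestamp are
    parsed from the filename when it follows the naming convention.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises bare ValueError on bad files
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim > 1:
        warnings.warn(f"{path.name}: multi-channel input, keeping channel 1")
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / _FULL_SCALE
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float WAV
        samples = np.asarray(data, dtype=np.float64)
    samples = np.clip(samples, -1.0, 1.0)
    meta = parse_clip_filename(path.name)
    site, ts = meta if meta is not None else ("", None)
    return AudioClip(samples, float(rate), clip_id=path.stem, site=site, timestamp=ts)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write an :class:`AudioClip` as PCM 16-bit mono WAV."""
    data = np.clip(np.round(clip.samples * _FULL_SCALE), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), int(clip.sample_rate), data)


def _frame_signal(x: np.ndarray, window_length: int, hop: int) -> np.ndarray:
    n_frames = 1 + (x.size - window_length) // hop
    idx = np.arange(window_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def compute_spectrogram(
    clip: AudioClip, window_length: int = 512, overlap: float = 0.0
) -> Spectrogram:
    """Magnitude STFT with a periodic Hann window.

    Frequency resolution is ``sample_rate / window_length``; frames are
    ``window_length`` samples stepped by ``window_length * (1 - overlap)``.
    """
    if window_length > clip.samples.size:
        raise ValueError("window_length exceeds clip length")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    hop = max(1, int(round(window_length * (1.0 - overlap))))
    window = get_window("hann", window_length, fftbins=True)
    frames = _frame_signal(clip.samples, window_length, hop)
    amp = np.abs(np.fft.rfft(frames * window, axis=1)).T
    freqs = np.fft.rfftfreq(window_length, d=1.0 / clip.sample_rate)
    times = (np.arange(frames.shape[0]) * hop + window_length / 2) / clip.sample_rate
    return Spectrogram(amp, freqs, times, window_length, overlap)


def bandpass_filter(
    clip: AudioClip, f_low: float = 3000.0, f_high: float = 10000.0
) -> AudioClip:
    """Brick-wall band-pass via FFT-domain masking (zero-phase).

    Components outside [f_low, f_high] are zeroed; passband gain is unity.
    """
    nyquist = clip.sample_rate / 2.0
    if not 0 <= f_low < f_high <= nyquist:
        raise ValueError(f"invalid band [{f_low}, {f_high}] for Nyquist {nyquist}")
    spectrum = np.fft.rfft(clip.samples)
    freqs = np.fft.rfftfreq(clip.samples.size, d=1.0 / clip.sample_rate)
    mask = (freqs >= f_low) & (freqs <= f_high)
    filtered = np.fft.irfft(spectrum * mask, n=clip.samples.size)
    # masking cannot raise the peak above full scale materially, but guard
    peak = np.max(np.abs(filtered))
    if peak > 1.0:
        filtered = filtered / peak
    return clip.with_samples(filtered)


def mean_spectrum(
    clip: AudioClip, window_length: int = 512, overlap: float = 0.0
) -> MeanSpectrum:
    """Amplitude-corrected mean spectrum, normalized to a maximum of 1.

    The time-average of STFT magnitudes is scaled by the Hann amplitude
    correction (2 / sum(window)); a silent clip returns a zero vector with
    ``silent=True`` instead of dividing by zero.
    """
    spec = compute_spectrogram(clip, window_length, overlap)
    window = get_window("hann", window_length, fftbins=True)
    mean_amp = spec.amplitude.mean(axis=1) * (2.0 / window.sum())
    peak = mean_amp.max()
    if peak <= 0:
        return MeanSpectrum(spec.freq_axis, np.zeros_like(mean_amp), silent=True)
    return MeanSpectrum(spec.freq_axis, mean_amp / peak, silent=False)


def amplitude_envelope(clip: AudioClip) -> np.ndarray:
    """Analytic-signal magnitude (Hilbert envelope), same length as input."""
    return np.abs(hilbert(clip.samples))
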