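"""The five band-limited acoustic indices and their min-max scaling.

All indices are restricted to the insect band (3-10 kHz by default), where
tropical cricket and katydid biophony concentrates:

* **ACI** (acoustic complexity): per frequency bin and 5-s temporal chunk,
  the sum of absolute successive-frame amplitude differences divided by the
  chunk's amplitude sum, totalled over bins and chunks.
* **ADI** (acoustic diversity): Shannon entropy (natural log) of the
  proportional occupancy of 1-kHz bands, occupancy being the fraction of
  spectrogram cells above a dBFS threshold.
* **BI** (bioacoustic index): area of the band's mean dB spectrum above its
  quietest bin, in dB * kHz.
* **H** (acoustic entropy): product of normalized spectral entropy (mean
  spectrum as a PMF) and normalized temporal entropy (amplitude envelope
  as a PMF); in [0, 1].
* **NP**: count of mean-spectrum peaks inside the band.

Following the original recipe order, ADI and H are computed on a clip
already band-pass filtered to 3-10 kHz, while ACI, BI and NP take band
limits as arguments. Scaling maps each index affinely onto
[0.0001, 0.9999] over a table of clips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .audio import (
    AudioClip,
    MeanSpectrum,
    Spectrogram,
    amplitude_envelope,
    bandpass_filter,
    compute_spectrogram,
    mean_spectrum,
)

__all__ = [
    "IndexVector",
    "compute_aci",
    "compute_adi",
    "band_occupancy",
    "compute_bi",
    "compute_h",
    "spectral_entropy",
    "temporal_entropy",
    "compute_np",
    "compute_indices",
    "IndexScaler",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ["aci", "adi", "bi", "h", "np"]


@dataclass
class IndexVector:
    """The five per-clip index values plus a silence flag."""

    clip_id: str
    aci: float
    adi: float
    bi: float
    h: float
    np_peaks: int
    silent: bool = False


def compute_aci(
    spec: Spectrogram,
    f_min: float = 3000.0,
    f_max: float = 10000.0,
    chunk: float = 5.0,
) -> float:
    """Acoustic complexity index over [f_min, f_max], chunked in time.

    For each bin and chunk, d = sum_k |I_k - I_{k+1}| / sum_k I_k; chunks
    whose amplitude sum is zero contribute 0. ACI is the grand total.
    """
    rows = spec.band(f_min, f_max)
    if not rows.any():
        raise ValueError(f"no frequency bins inside [{f_min}, {f_max}]")
    amp = spec.amplitude[rows]
    if spec.n_frames > 1:
        frame_dt = float(spec.time_axis[1] - spec.time_axis[0])
    else:
        frame_dt = spec.window_length  # single frame: one chunk regardless
    frames_per_chunk = max(2, int(round(chunk / frame_dt)))
    total = 0.0
    for start in range(0, amp.shape[1], frames_per_chunk):
        block = amp[:, start : start + frames_per_chunk]
        if block.shape[1] < 2:
            continue
        sums = block.sum(axis=1)
        diffs = np.abs(np.diff(block, axis=1)).sum(axis=1)
        nz = sums > 0
        total += float((diffs[nz] / sums[nz]).sum())
    return total


def band_occupancy(
    spec: Spectrogram,
    max_freq: float = 10000.0,
    band_width: float = 1000.0,
    db_threshold: float = -50.0,
) -> np.ndarray:
    """Fraction of cells above ``db_threshold`` (dB re spectrogram max) per band."""
    peak = spec.amplitude.max()
    n_bands = int(np.ceil(max_freq / band_width))
    occ = np.zeros(n_bands)
    if peak <= 0:
        return occ
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(spec.amplitude / peak)
    for i in range(n_bands):
        rows = (spec.freq_axis >= i * band_width) & (
            spec.freq_axis < (i + 1) * band_width
        )
        if rows.any():
            occ[i] = float(np.mean(db[rows] > db_threshold))
    return occ


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def compute_adi(
    clip: AudioClip,
    max_freq: float = 10000.0,
    band_width: float = 1000.0,
    db_threshold: float = -50.0,
    window_length: int = 512,
) -> float:
    """Acoustic diversity: entropy (nats) of proportional 1-kHz band occupancy.

    The clip is expected to be already band-pass filtered (3-10 kHz in the
    standard pipeline); bands emptied by the filter count zero occupancy,
    which deflates ADI relative to an unfiltered computation.
    """
    spec = compute_spectrogram(clip, window_length)
    occ = band_occupancy(spec, max_freq, band_width, db_threshold)
    total = occ.sum()
    if total <= 0:
        return 0.0
    return _shannon(occ / total)


def compute_bi(
    spec: Spectrogram, f_min: float = 3000.0, f_max: float = 10000.0
) -> float:
    """Bioacoustic index: area of the band mean dB spectrum above its minimum."""
    rows = spec.band(f_min, f_max)
    if not rows.any():
        raise ValueError(f"no frequency bins inside [{f_min}, {f_max}]")
    mean_amp = spec.amplitude[rows].mean(axis=1)
    if mean_amp.max() <= 0:
        return 0.0
    floor = mean_amp[mean_amp > 0].min() * 1e-12  # avoid -inf for exact zeros
    db = 20.0 * np.log10(np.maximum(mean_amp, floor))
    bin_width_khz = float(spec.freq_axis[1] - spec.freq_axis[0]) / 1000.0
    return float((db - db.min()).sum() * bin_width_khz)


def spectral_entropy(ms: MeanSpectrum) -> float:
    """Shannon entropy of the mean spectrum PMF, normalized by log(bin count)."""
    amp = ms.amplitude
    total = amp.sum()
    if total <= 0 or amp.size < 2:
        return 0.0
    return _shannon(amp / total) / np.log(amp.size)


def temporal_entropy(envelope: np.ndarray) -> float:
    """Shannon entropy of the amplitude-envelope PMF, normalized by log(length)."""
    env = np.asarray(envelope, dtype=np.float64)
    total = env.sum()
    if total <= 0 or env.size < 2:
        return 0.0
    return _shannon(env / total) / np.log(env.size)


def compute_h(clip: AudioClip, window_length: int = 512) -> float:
    """Acoustic entropy H = Hf * Ht in [0, 1].

    Hf is the normalized entropy of the mean spectrum, Ht of the Hilbert
    amplitude envelope. The clip is expected pre-filtered to the insect
    band. Silence yields 0.
    """
    ms = mean_spectrum(clip, window_length)
    if ms.silent:
        return 0.0
    hf = spectral_entropy(ms)
    ht = temporal_entropy(amplitude_envelope(clip))
    return float(hf * ht)


def compute_np(
    ms: MeanSpectrum,
    low_cut: float = 300.0,
    count_band: tuple[float, float] = (3000.0, 10000.0),
    peak_threshold: float = 0.01,
) -> int:
    """Count mean-spectrum peaks strictly inside ``count_band``.

    Local maxima of the mean spectrum above ``low_cut`` Hz with amplitude
    prominence of at least ``peak_threshold`` (fraction of the spectrum
    maximum) are detected; only peaks with ``count_band[0] < f <
    count_band[1]`` are counted.
    """
    keep = ms.freq_axis > low_cut
    amp = ms.amplitude[keep]
    freqs = ms.freq_axis[keep]
    if amp.size < 3 or amp.max() <= 0:
        return 0
    locs, _ = find_peaks(amp, prominence=peak_threshold * amp.max())
    f = freqs[locs]
    return int(np.sum((f > count_band[0]) & (f < count_band[1])))


def compute_indices(
    clip: AudioClip,
    f_min: float = 3000.0,
    f_max: float = 10000.0,
    window_length: int = 512,
    aci_chunk: float = 5.0,
    adi_threshold: float = -50.0,
    np_low_cut: float = 300.0,
    np_peak_threshold: float = 0.01,
    silence_rms: float = 1e-4,
) -> IndexVector:
    """Compute all five indices for one clip, following the recipe order.

    ACI and BI are taken from the raw clip's spectrogram with band limits;
    ADI and H are computed on the band-pass filtered clip; NP on the raw
    mean spectrum above ``np_low_cut``, counting the insect band only.
    Clips with RMS below ``silence_rms`` are flagged silent (indices set
    to 0 and excluded from scaling downstream).
    """
    rms = float(np.sqrt(np.mean(clip.samples**2)))
    if rms < silence_rms:
        return IndexVector(clip.clip_id, 0.0, 0.0, 0.0, 0.0, 0, silent=True)
    spec = compute_spectrogram(clip, window_length)
    filtered = bandpass_filter(clip, f_min, f_max)
    ms = mean_spectrum(clip, window_length)
    return IndexVector(
        clip_id=clip.clip_id,
        aci=compute_aci(spec, f_min, f_max, aci_chunk),
        adi=compute_adi(filtered, max_freq=f_max, db_threshold=adi_threshold,
                        window_length=window_length),
        bi=compute_bi(spec, f_min, f_max),
        h=compute_h(filtered, window_length),
        np_peaks=compute_np(ms, np_low_cut, (f_min, f_max), np_peak_threshold),
        silent=False,
    )


class IndexScaler(TransformerMixin, BaseEstimator):
    """Min-max scale each index column onto [lo, hi] = [0.0001, 0.9999].

    The affine map ``x' = lo + (x - min) / (max - min) * (hi - lo)`` is fit
    per column over a table of clips; the stored (min, max) make it
    invertible and reusable on new data.
    """

    def __init__(self, lo: float = 0.0001, hi: float = 0.9999):
        self.lo = lo
        self.hi = hi

    def fit(self, X, y=None):
        X = self._as_array(X)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        degenerate = np.flatnonzero(self.max_ - self.min_ <= 0)
        if degenerate.size:
            cols = (
                [self.columns_[i] for i in degenerate]
                if hasattr(self, "columns_")
                else list(degenerate)
            )
            raise ValueError(f"constant index column(s), cannot scale: {cols}")
        return self

    def transform(self, X):
        check_is_fitted(self, "min_")
        arr = self._as_array(X, fit=False)
        scaled = self.lo + (arr - self.min_) / (self.max_ - self.min_) * (
            self.hi - self.lo
        )
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(scaled, index=X.index, columns=self.columns_)
        return scaled

    def inverse_transform(self, X):
        check_is_fitted(self, "min_")
        arr = np.asarray(X, dtype=np.float64)
        raw = self.min_ + (arr - self.lo) / (self.hi - self.lo) * (
            self.max_ - self.min_
        )
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(raw, index=X.index, columns=self.columns_)
        return raw

    def _as_array(self, X, fit: bool = True) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if fit:
                self.columns_ = list(X.columns)
            return X.to_numpy(dtype=np.float64)
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D table of index values")
        return arr
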