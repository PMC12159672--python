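"""Quality-control screening of recordings.

Two stages, run in this order:

1. **Rain screening** — a simplified two-band classifier in the spirit of
   threshold-based hard-rain detectors: mean band power (PSD) and band
   signal-to-noise ratio (temporal mean/SD of band amplitude) in
   0.6-1.2 kHz and 4.4-5.6 kHz. Heavy rain is broadband, steady and
   low-frequency weighted, so all four metrics sit high simultaneously;
   thresholds are calibrated as shrunk minima over known rain clips.
2. **Mahalanobis screening** — squared Mahalanobis distance of each
   clip's five-index vector from the corpus mean under the sample
   covariance; clips with squared distance above 12 are removed. The
   distance is affine-invariant per column, so it is identical on raw
   and min-max-scaled indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_is_fitted

from .audio import AudioClip, compute_spectrogram
from .indices import INDEX_COLUMNS

__all__ = ["RainMetrics", "rain_metrics", "RainClassifier", "MahalanobisScreen"]

RAIN_BAND_LOW = (600.0, 1200.0)
RAIN_BAND_MID = (4400.0, 5600.0)


@dataclass
class RainMetrics:
    psd_low: float
    psd_mid: float
    snr_low: float
    snr_mid: float

    def as_array(self) -> np.ndarray:
        return np.array([self.psd_low, self.psd_mid, self.snr_low, self.snr_mid])


def rain_metrics(clip: AudioClip, window_length: int = 512) -> RainMetrics:
    """Band PSD and band SNR for the two rain-diagnostic bands.

    PSD is the mean squared spectrogram amplitude over the band; SNR is
    the temporal mean/SD ratio of the band-average amplitude (steady
    rain gives a high ratio, impulsive biophony a low one).
    """
    if clip.sample_rate < 2 * RAIN_BAND_MID[1]:
        raise ValueError("sample rate too low for the 4.4-5.6 kHz rain band")
    spec = compute_spectrogram(clip, window_length)

    def band_stats(lo: float, hi: float) -> tuple[float, float]:
        rows = spec.band(lo, hi)
        amp = spec.amplitude[rows]
        series = amp.mean(axis=0)
        sd = series.std()
        snr = float(series.mean() / sd) if sd > 0 else 0.0
        return float(np.mean(amp**2)), snr

    psd_low, snr_low = band_stats(*RAIN_BAND_LOW)
    psd_mid, snr_mid = band_stats(*RAIN_BAND_MID)
    return RainMetrics(psd_low, psd_mid, snr_low, snr_mid)


class RainClassifier(BaseEstimator):
    """Threshold classifier for heavy rain, calibrated on known rain clips.

    ``fit`` takes a table (or array) of the four rain metrics computed on
    clips known to contain rain; thresholds are the per-metric minima
    shrunk by ``safety_factor``. ``predict`` flags a clip as rain when
    all four metrics meet their thresholds.
    """

    METRICS = ["psd_low", "psd_mid", "snr_low", "snr_mid"]

    def __init__(self, safety_factor: float = 0.95, min_training: int = 10):
        self.safety_factor = safety_factor
        self.min_training = min_training

    def fit(self, X, y=None):
        X = self._coerce(X)
        if X.shape[0] < self.min_training:
            raise ValueError(
                f"need >= {self.min_training} rain clips to calibrate, got {X.shape[0]}"
            )
        self.thresholds_ = X.min(axis=0) * self.safety_factor
        return self

    def predict(self, X) -> np.ndarray:
        """Boolean rain flag per row."""
        check_is_fitted(self, "thresholds_")
        X = self._coerce(X)
        return np.all(X >= self.thresholds_, axis=1)

    @staticmethod
    def _coerce(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[RainClassifier.METRICS]
        arr = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if arr.shape[1] != 4:
            raise ValueError("expected 4 rain metrics per clip")
        return arr


class MahalanobisScreen(OutlierMixin, BaseEstimator):
    """Multivariate outlier screen on the five-index vectors.

    The mean and (non-robust) sample covariance are estimated on *all*
    supplied clips, outliers included; a clip is retained when its
    squared Mahalanobis distance is at most ``threshold`` (default 12).
    Re-running on the retained set with the fitted mean/covariance flags
    nothing new (idempotence).
    """

    def __init__(self, threshold: float = 12.0, columns: list[str] | None = None):
        self.threshold = threshold
        self.columns = columns

    def fit(self, X, y=None):
        arr, cols = self._coerce(X)
        if arr.shape[0] < arr.shape[1] + 1:
            raise ValueError("need at least n_features + 1 clips")
        self.mean_ = arr.mean(axis=0)
        self.covariance_ = np.cov(arr, rowvar=False)
        # work on the correlation scale: numerically stable and manifestly
        # invariant under affine rescaling of individual columns
        sd = np.sqrt(np.diag(self.covariance_))
        if np.any(sd <= 0):
            bad = [cols[i] for i in np.flatnonzero(sd <= 0)]
            raise ValueError(f"constant (collinear) index columns: {bad}")
        corr = self.covariance_ / np.outer(sd, sd)
        cond = np.linalg.cond(corr)
        if not np.isfinite(cond) or cond > 1e10:
            pairs = [
                (cols[i], cols[j])
                for i in range(len(cols))
                for j in range(i + 1, len(cols))
                if abs(corr[i, j]) > 0.999
            ]
            raise ValueError(
                f"singular index covariance; collinear columns: {pairs or cols}"
            )
        self._sd_ = sd
        self._corr_precision_ = np.linalg.inv(corr)
        self.feature_names_ = cols
        return self

    def mahalanobis_sq(self, X) -> np.ndarray:
        """Squared Mahalanobis distance of each row from the fitted mean."""
        check_is_fitted(self, "mean_")
        arr, _ = self._coerce(X)
        z = (arr - self.mean_) / self._sd_
        return np.einsum("ij,jk,ik->i", z, self._corr_precision_, z)

    def predict(self, X) -> np.ndarray:
        """+1 for retained clips, -1 for outliers (sklearn convention)."""
        return np.where(self.mahalanobis_sq(X) <= self.threshold, 1, -1)

    def retained(self, X) -> np.ndarray:
        return self.mahalanobis_sq(X) <= self.threshold

    def _coerce(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            cols = self.columns or [c for c in INDEX_COLUMNS if c in X.columns]
            if not cols:
                cols = list(X.columns)
            return X[cols].to_numpy(dtype=np.float64), cols
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("expected 2-D index table")
        return arr, [str(i) for i in range(arr.shape[1])]


def qc_report(
    index_table: pd.DataFrame,
    rain_flags: np.ndarray,
    screen: MahalanobisScreen,
) -> pd.DataFrame:
    """Combine rain flags and Mahalanobis distances into a QC table.

    ``retained`` means not rain-flagged and within the distance threshold.
    ``qc_label`` buckets clips: 'problematic' (outlier), 'intermediate'
    (rain-flagged but within threshold) and 'normal'.
    """
    d2 = screen.mahalanobis_sq(index_table)
    retained = (~rain_flags) & (d2 <= screen.threshold)
    label = np.where(
        d2 > screen.threshold,
        "problematic",
        np.where(rain_flags, "intermediate", "normal"),
    )
    out = index_table[["clip_id"]].copy() if "clip_id" in index_table else pd.DataFrame(
        index=index_table.index
    )
    out["rain_flag"] = rain_flags
    out["mahalanobis_sq"] = d2
    out["qc_label"] = label
    out["retained"] = retained
    return out
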