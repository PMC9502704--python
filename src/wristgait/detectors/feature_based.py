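"""Windowed feature-threshold gait classifier.

The classic pipeline: cut the recording into 6 s windows, compute the
DC-removed Euclidean norm per window, gate out low-activity windows with a
1 m/s^2 amplitude rule, then apply time/frequency-domain feature rules — the
dominant spectral peak must fall in the 0.5-3 Hz locomotor band, carry a
minimum fraction of total power, and stand out from the band floor. The
output is a hard binary decision per window (no probability), so this
detector is excluded from ROC/PR analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from ..io import AccelRecording
from ..preprocessing import WindowSet, segment_windows
from .base import DetectorResults

__all__ = ["FBFeatureVector", "FBThresholds", "compute_features",
           "classify_window", "FeatureBasedDetector", "FBResults"]

LOCOMOTOR_BAND = (0.5, 3.0)


@dataclass
class FBFeatureVector:
    window_rms: float           # m/s^2, DC-removed norm
    window_std: float           # m/s^2
    dominant_freq: float        # Hz, over 0.1 Hz .. Nyquist
    locomotor_peak_freq: float  # Hz, within the 0.5-3 Hz band
    locomotor_band_ratio: float  # fraction of total PSD power in band
    peak_prominence: float      # dominant in-band peak over mean band power
    degenerate: bool = False    # all-zero window


@dataclass
class FBThresholds:
    activity_threshold: float = 1.0  # m/s^2 window-RMS gate
    band: tuple[float, float] = LOCOMOTOR_BAND
    min_band_ratio: float = 0.4
    min_peak_prominence: float = 3.0

    def __post_init__(self) -> None:
        if self.activity_threshold <= 0:
            raise ValueError("activity_threshold must be positive")


def compute_features(window: np.ndarray, fs: float) -> FBFeatureVector:
    """Features of one (3, L) window, computed on the DC-removed Euclidean
    norm with a Hann-tapered periodogram."""
    window = np.asarray(window, dtype=float)
    if window.shape[0] != 3:
        raise ValueError("window must be (3, L)")
    if window.shape[1] < 2 * fs:
        raise ValueError("window must cover at least 2 s")
    norm = np.sqrt((window**2).sum(axis=0))
    norm = norm - norm.mean()
    if not norm.any():
        return FBFeatureVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    rms = float(np.sqrt((norm**2).mean()))
    std = float(norm.std())
    freqs, psd = sp_signal.periodogram(norm, fs=fs, window="hann")
    total = psd.sum()
    searchable = freqs >= 0.1
    dom = float(freqs[searchable][np.argmax(psd[searchable])])
    band = (freqs >= LOCOMOTOR_BAND[0]) & (freqs <= LOCOMOTOR_BAND[1])
    band_psd = psd[band]
    peak_idx = int(np.argmax(band_psd))
    loco_peak = float(freqs[band][peak_idx])
    ratio = float(band_psd.sum() / total) if total > 0 else 0.0
    mean_band = band_psd.mean() if band_psd.size else 0.0
    prominence = float(band_psd[peak_idx] / mean_band) if mean_band > 0 else 0.0
    return FBFeatureVector(rms, std, dom, loco_peak, ratio, prominence)


def classify_window(features: FBFeatureVector, th: FBThresholds) -> bool:
    """Gait iff the window passes the activity gate AND the dominant
    frequency is in-band AND band power and peak prominence clear their
    minima."""
    if features.degenerate:
        return False
    return (
        features.window_rms >= th.activity_threshold
        and th.band[0] <= features.dominant_freq <= th.band[1]
        and features.locomotor_band_ratio >= th.min_band_ratio
        and features.peak_prominence >= th.min_peak_prominence
    )


class FeatureBasedDetector:
    """Rule-based detector; ``fit`` only freezes the thresholds (no
    learning, as in the source design)."""

    def __init__(self, thresholds: FBThresholds | None = None,
                 window_s: float = 6.0, overlap: float = 0.5):
        self.thresholds = thresholds or FBThresholds()
        self.window_s = window_s
        self.overlap = overlap

    def fit(self) -> "FBResults":
        return FBResults(thresholds=self.thresholds, window_s=self.window_s,
                         overlap=self.overlap)


@dataclass
class FBResults(DetectorResults):
    thresholds: FBThresholds = field(default_factory=FBThresholds)
    window_s: float = 6.0
    overlap: float = 0.5
    granularity: str = "window"
    continuous: bool = False  # hard decisions: no ROC/PR

    def predict_windows(self, ws: WindowSet) -> np.ndarray:
        return np.array(
            [
                classify_window(compute_features(w, ws.fs), self.thresholds)
                for w in ws.windows
            ],
            dtype=np.int8,
        )

    def predict_proba(self, ws: WindowSet) -> np.ndarray:
        """0/1 pseudo-probabilities (binary decision per window)."""
        return self.predict_windows(ws).astype(float)

    def predict_recording(self, rec: AccelRecording) -> tuple[np.ndarray, WindowSet]:
        ws = segment_windows(rec, self.window_s, self.overlap, remove_dc=False)
        return self.predict_windows(ws), ws

    def _summary_rows(self):
        t = self.thresholds
        return [
            ("activity threshold (m/s^2)", t.activity_threshold),
            ("locomotor band (Hz)", t.band),
            ("min band ratio", t.min_band_ratio),
            ("min peak prominence", t.min_peak_prominence),
            ("window (s)", self.window_s),
        ]
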