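"""Gait quantity and gait quality measures with daily aggregation.

Quantity: minutes of detected walking per calendar day, restricted to wear
days with at least 8 h of recording, compared against reference daily
minutes by Pearson correlation.

Quality (per bout, bouts longer than 10 s only):
  - dominant frequency: location (Hz) of the largest Welch-PSD peak of the
    DC-removed acceleration norm inside the 0.5-3 Hz locomotor band;
  - amplitude of the dominant frequency: that peak's power normalized by
    the total signal power (unitless), i.e. how strongly the rhythm
    dominates the signal;
  - RMS (m/s^2) of the DC-removed norm, a gait-intensity measure;
  - stride regularity: the biased, zero-lag-normalized autocorrelation of
    the DC-removed norm evaluated at the stride lag (the dominant
    autocorrelation peak between one half and twice the dominant period);
    1 = perfectly repeating strides.

Per-bout values are aggregated as daily medians, then per-subject medians
of the daily values; group summaries are mean +/- SD across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .io import AccelRecording, extract_bouts
from .preprocessing import euclidean_norm

__all__ = [
    "DailyQuantity", "GaitQualityRecord",
    "daily_walking_minutes", "pearson_r", "bout_quality",
    "quality_from_recording", "aggregate_quality", "quality_agreement",
]

LOCOMOTOR_BAND = (0.5, 3.0)
MIN_WEAR_H = 8.0
MIN_QUALITY_BOUT_S = 10.0


@dataclass
class DailyQuantity:
    subject_id: str
    date: object
    wear_hours: float
    walking_minutes_predicted: float
    walking_minutes_reference: Optional[float] = None


def daily_walking_minutes(
    rec: AccelRecording,
    pred_mask: np.ndarray,
    min_wear_h: float = MIN_WEAR_H,
) -> list[DailyQuantity]:
    """Per-day walking minutes from a per-sample binary prediction mask
    (post high-precision threshold); days with under ``min_wear_h`` hours of
    recording are dropped. Reference minutes come from ``rec.mask`` when
    present."""
    pred_mask = np.asarray(pred_mask)
    if pred_mask.shape[0] != rec.n_samples:
        raise ValueError("pred_mask must align with the recording")
    days = rec.day_index()
    out = []
    for d in np.unique(days):
        sel = days == d
        wear_h = sel.sum() / rec.fs / 3600.0
        if wear_h < min_wear_h:
            continue
        pred_min = pred_mask[sel].sum() / rec.fs / 60.0
        ref_min = (rec.mask[sel].sum() / rec.fs / 60.0
                   if rec.mask is not None else None)
        out.append(DailyQuantity(rec.subject_id, rec.date_of_day(d), wear_h,
                                 float(pred_min), ref_min))
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GaitQualityRecord:
    bout_id: int
    bout_duration_s: float
    dominant_frequency: float   # Hz, in [0.5, 3]
    amplitude_dominant: float   # unitless (peak power / total power)
    rms: float                  # m/s^2
    stride_regularity: float    # in [-1, 1]
    subject_id: str = "S0"
    date: object = None


def bout_quality(bout_acc: np.ndarray, fs: float, bout_id: int = 0,
                 min_duration_s: float = MIN_QUALITY_BOUT_S) -> GaitQualityRecord:
    """Quality measures of one tri-axial bout (> 10 s)."""
    bout_acc = np.asarray(bout_acc, dtype=float)
    n = bout_acc.shape[0]
    if n / fs <= min_duration_s:
        raise ValueError(f"bout must exceed {min_duration_s} s")
    norm = euclidean_norm(bout_acc)
    x = norm - norm.mean()
    rms = float(np.sqrt((x**2).mean()))

    nper = min(int(4 * fs), n)  # Welch: 4 s Hann segments, 50% overlap
    freqs, psd = sp_signal.welch(x, fs=fs, nperseg=nper, window="hann")
    band = (freqs >= LOCOMOTOR_BAND[0]) & (freqs <= LOCOMOTOR_BAND[1])
    if not band.any() or psd[band].max() <= 0:
        raise ValueError("no spectral peak inside the locomotor band")
    k = int(np.argmax(psd[band]))
    dom_f = float(freqs[band][k])
    total = float(np.trapezoid(psd, freqs))
    # peak power: integrate one resolution bin around the peak
    df = freqs[1] - freqs[0]
    peak_power = float(psd[band][k] * df)
    amp = peak_power / total if total > 0 else 0.0

    # stride regularity: biased autocorrelation normalized at lag 0
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    ac = ac / ac[0]
    lag0 = fs / dom_f
    lo = max(int(round(0.5 * lag0)), 1)
    hi = min(int(round(2.0 * lag0)), n - 1)
    if hi <= lo:
        raise ValueError("bout too short to place the stride lag")
    seg = ac[lo : hi + 1]
    # dominant peak in the search window; fall back to the max value
    peaks, _ = sp_signal.find_peaks(seg)
    sr = float(seg[peaks].max()) if peaks.size else float(seg.max())
    return GaitQualityRecord(
        bout_id=bout_id, bout_duration_s=n / fs, dominant_frequency=dom_f,
        amplitude_dominant=amp, rms=rms, stride_regularity=sr,
    )


def quality_from_recording(
    rec: AccelRecording,
    pred_mask: np.ndarray,
    min_detect_bout_s: float = 6.0,
    min_quality_bout_s: float = MIN_QUALITY_BOUT_S,
) -> list[GaitQualityRecord]:
    """Quality records for every predicted bout longer than the quality
    threshold; bouts are reconstructed from the thresholded per-sample mask
    (>= 6 s detection rule first, then the > 10 s quality rule)."""
    bouts, _ = extract_bouts(pred_mask, rec.fs, min_detect_bout_s)
    days = rec.day_index()
    out = []
    for i, b in enumerate(bouts):
        if b.duration_s <= min_quality_bout_s:
            continue
        try:
            q = bout_quality(rec.acc[b.start : b.end], rec.fs, bout_id=i)
        except ValueError:
            continue
        q.subject_id = rec.subject_id
        q.date = rec.date_of_day(days[b.start])
        out.append(q)
    return out


MEASURES = ["dominant_frequency", "amplitude_dominant", "rms", "stride_regularity"]


def aggregate_quality(records: Sequence[GaitQualityRecord]) -> dict[str, pd.DataFrame]:
    """Daily medians per measure, per-subject medians of the daily values,
    and the group summary (mean +/- SD across subjects)."""
    if not records:
        raise ValueError("no quality records to aggregate")
    df = pd.DataFrame([vars(r) for r in records])
    daily = df.groupby(["subject_id", "date"])[MEASURES].median().reset_index()
    subject = daily.groupby("subject_id")[MEASURES].median()
    group = pd.DataFrame({"mean": subject.mean(), "sd": subject.std(ddof=1)})
    return {"per_bout": df, "daily": daily, "subject": subject, "group": group}


def quality_agreement(
    wrist_daily: pd.DataFrame,
    reference_daily: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and p per quality measure between paired daily values
    (matched on subject and date), with Bonferroni-adjusted significance."""
    merged = wrist_daily.merge(reference_daily, on=["subject_id", "date"],
                               suffixes=("_wrist", "_ref"))
    if len(merged) < 3:
        raise ValueError("fewer than 3 paired days")
    rows = []
    n_tests = len(MEASURES)
    for m in MEASURES:
        r, p = pearson_r(merged[f"{m}_wrist"], merged[f"{m}_ref"])
        rows.append({"measure": m, "r": r, "p": p, "n": len(merged),
                     "significant_bonferroni": p < alpha / n_tests})
    return pd.DataFrame(rows).set_index("measure")
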