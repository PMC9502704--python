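"""Recording data model, delimited-text readers/writers, label resampling
and gait-bout extraction.

A recording is a uniformly sampled tri-axial acceleration series in m/s^2,
optionally carrying a per-sample binary gait mask (the reference annotation,
e.g. derived from a lower-back sensor and downsampled to the wrist rate by
nearest-neighbour interpolation). Gait bouts are maximal runs of mask==1;
runs shorter than a minimum duration (6 s by default) are too short to
detect or to compute quality measures on and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

G_TO_MS2 = 9.80665

__all__ = [
    "AccelRecording",
    "BoutInterval",
    "read_recording",
    "write_recording",
    "resample_mask",
    "extract_bouts",
    "write_bouts",
]


@dataclass
class BoutInterval:
    """Half-open sample interval [start, end) of a single gait bout."""

    start: int
    end: int
    duration_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid bout interval [{self.start}, {self.end})")
        if self.duration_s <= 0:
            raise ValueError("bout duration must be positive")


@dataclass
class AccelRecording:
    """A uniformly sampled tri-axial acceleration time series.

    Parameters
    ----------
    acc : (N, 3) float array, m/s^2, axes x, y, z.
    fs : sampling rate in Hz (> 0).
    subject_id : subject identifier.
    t0 : recording start time; defaults to midnight (day boundaries for the
        daily measures are wall-clock midnights relative to t0).
    wear_site : "wrist" or "lower_back".
    mask : optional (N,) int array of {0, 1} per-sample gait labels.
    """

    acc: np.ndarray
    fs: float
    subject_id: str = "S0"
    t0: datetime = field(default_factory=lambda: datetime(2000, 1, 1))
    wear_site: str = "wrist"
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must be an (N, 3) array")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.wear_site not in ("wrist", "lower_back"):
            raise ValueError(f"unknown wear_site {self.wear_site!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != (self.acc.shape[0],):
                raise ValueError("mask length must equal number of samples")
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask values must be 0 or 1")
            self.mask = self.mask.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds since t0."""
        return np.arange(self.n_samples) / self.fs

    def day_index(self) -> np.ndarray:
        """Calendar-day index of every sample (0 = day of t0), split at
        wall-clock midnight."""
        offset_s = (
            self.t0 - self.t0.replace(hour=0, minute=0, second=0, microsecond=0)
        ).total_seconds()
        return ((offset_s + self.times()) // 86400.0).astype(int)

    def date_of_day(self, day: int):
        return (self.t0 + timedelta(days=int(day))).date()

    def with_mask(self, mask: np.ndarray) -> "AccelRecording":
        return replace(self, mask=mask)


def read_recording(
    path,
    fs: float,
    wear_site: str = "wrist",
    subject_id: str = "S0",
    t0: Optional[datetime] = None,
    unit: str = "ms2",
) -> AccelRecording:
    """Read a delimited-text recording: columns ``x,y,z[,label]``.

    The header row is optional and detected automatically. ``unit="g"``
    converts acceleration columns to m/s^2 (x 9.80665) at read time; the
    optional 4th column must be binary and becomes the gait mask.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty file")
    # optional header: first row non-numeric
    first = df.iloc[0]
    if any(pd.to_numeric(first, errors="coerce").isna()):
        df = df.iloc[1:].reset_index(drop=True)
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no data rows")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected >=3 numeric columns, got {df.shape[1]}")
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.iloc[:, :3].isna().any().any():
        raise ValueError(f"{path}: non-numeric acceleration rows")
    acc = vals.iloc[:, :3].to_numpy(dtype=float)
    if unit == "g":
        acc = acc * G_TO_MS2
    elif unit != "ms2":
        raise ValueError(f"unknown unit {unit!r}")
    mask = None
    if df.shape[1] >= 4:
        lab = vals.iloc[:, 3]
        if lab.isna().any() or not np.isin(lab.to_numpy(), (0.0, 1.0)).all():
            raise ValueError(f"{path}: label column must contain only 0/1")
        mask = lab.to_numpy().astype(np.int8)
    kwargs = {} if t0 is None else {"t0": t0}
    return AccelRecording(
        acc=acc, fs=fs, subject_id=subject_id, wear_site=wear_site, mask=mask, **kwargs
    )


def write_recording(rec: AccelRecording, path) -> None:
    """Write ``x,y,z[,label]`` delimited text (CSV, header row included)."""
    cols = {"x": rec.acc[:, 0], "y": rec.acc[:, 1], "z": rec.acc[:, 2]}
    if rec.mask is not None:
        cols["label"] = rec.mask
    pd.DataFrame(cols).to_csv(path, index=False)


def resample_mask(mask: Sequence[int], fs_src: float, fs_dst: float) -> np.ndarray:
    """Nearest-neighbour resampling of a binary label sequence from fs_src
    down to fs_dst.

    Output sample j (time j/fs_dst) takes the value of the nearest source
    sample; an exact tie between two source samples resolves to the earlier
    one. Upsampling (fs_dst > fs_src) is out of contract.
    """
    if not (fs_src >= fs_dst > 0):
        raise ValueError("requires fs_src >= fs_dst > 0")
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    n_src = mask.shape[0]
    n_dst = int(round(n_src * fs_dst / fs_src))
    j = np.arange(n_dst)
    # nearest source index to time j/fs_dst; ties -> earlier sample
    src_pos = j * (fs_src / fs_dst)
    idx = np.floor(src_pos + 0.5 - 1e-12).astype(int)
    idx = np.clip(idx, 0, n_src - 1)
    return mask[idx].astype(np.int8)


def extract_bouts(
    mask: Sequence[int], fs: float, min_duration_s: float = 6.0
) -> tuple[list[BoutInterval], np.ndarray]:
    """Convert maximal runs of 1s into bout intervals, dropping runs shorter
    than ``min_duration_s``.

    Returns ``(bouts, filtered_mask)`` where dropped runs are relabelled 0
    in the filtered mask. A run of exactly the minimum duration is retained.
    """
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be >= 0")
    mask = np.asarray(mask).astype(np.int8)
    if mask.size and not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    filtered = mask.copy()
    bouts: list[BoutInterval] = []
    if mask.size == 0:
        return bouts, filtered
    padded = np.concatenate(([0], mask, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    min_len = min_duration_s * fs
    for s, e in zip(starts, ends):
        dur = (e - s) / fs
        if (e - s) + 1e-9 >= min_len:
            bouts.append(BoutInterval(start=int(s), end=int(e), duration_s=dur))
        else:
            filtered[s:e] = 0
    return bouts, filtered


def write_bouts(bouts: Sequence[BoutInterval], path) -> None:
    """Export bouts as delimited text ``start_sample,end_sample,duration_s``."""
    pd.DataFrame(
        [(b.start, b.end, b.duration_s) for b in bouts],
        columns=["start_sample", "end_sample", "duration_s"],
    ).to_csv(path, index=False)
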