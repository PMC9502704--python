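"""Shared signal-conditioning chain.

Euclidean norm -> moving-STD activity gate -> (optional per-sample PCA
across axes) -> fixed-width overlapping windows with per-window DC removal
-> train-statistics normalization -> subject-disjoint fold construction.

The activity gate operates on the Euclidean norm in non-overlapping 3 s
blocks: blocks whose standard deviation falls below 0.1 m/s^2 are flagged
as low activity. Detectors that consume gated data (the flow-based anomaly
detector and the AR-HMM segmenter) excise the removed samples before
windowing; the supervised deep detectors consume ungated windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .io import AccelRecording

__all__ = [
    "WindowSet",
    "NormStats",
    "PCAProjection",
    "FoldSplit",
    "euclidean_norm",
    "activity_gate",
    "apply_gate",
    "segment_windows",
    "label_windows",
    "bandpower_features",
    "fit_norm_stats",
    "apply_norm",
    "inverse_norm",
    "fit_pca",
    "apply_pca",
    "make_folds",
]


def euclidean_norm(acc: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2) of an (N, 3) array."""
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("expected an (N, 3) array")
    return np.sqrt((acc**2).sum(axis=1))


def activity_gate(
    norm: np.ndarray, fs: float, window_s: float = 3.0, std_threshold: float = 0.1
) -> np.ndarray:
    """Boolean keep-mask: samples in non-overlapping ``window_s`` blocks with
    STD < ``std_threshold`` (m/s^2) are flagged removed (False)."""
    norm = np.asarray(norm, dtype=float)
    block = int(round(window_s * fs))
    if block < 2:
        raise ValueError("gate window must cover at least 2 samples")
    keep = np.ones(norm.shape[0], dtype=bool)
    for s in range(0, norm.shape[0], block):
        seg = norm[s : s + block]
        if seg.size >= 2 and seg.std() < std_threshold:
            keep[s : s + block] = False
        elif seg.size < 2:
            keep[s : s + block] = False
    return keep


def apply_gate(rec: AccelRecording, keep: np.ndarray) -> tuple[AccelRecording, np.ndarray]:
    """Excise removed samples; returns the gated recording plus the original
    indices of retained samples (for mapping predictions back)."""
    idx = np.flatnonzero(keep)
    mask = rec.mask[idx] if rec.mask is not None else None
    gated = AccelRecording(
        acc=rec.acc[idx], fs=rec.fs, subject_id=rec.subject_id,
        t0=rec.t0, wear_site=rec.wear_site, mask=mask,
    )
    return gated, idx


@dataclass
class WindowSet:
    """Fixed-width overlapping windows cut from one recording.

    ``windows`` has shape (W, 3, L); ``starts`` holds each window's start
    sample in the (possibly gated) source signal.
    """

    windows: np.ndarray
    fs: float
    window_s: float
    overlap: float
    starts: np.ndarray
    recording_id: str = "S0"
    labels: Optional[np.ndarray] = None
    kept: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.windows.ndim != 3 or self.windows.shape[1] != 3:
            raise ValueError("windows must be (W, 3, L)")
        if self.labels is not None and len(self.labels) != self.n_windows:
            raise ValueError("labels length mismatch")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]

    @property
    def hop(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap)))

    def flattened(self) -> np.ndarray:
        """(W, 3*L) feature matrix."""
        return self.windows.reshape(self.n_windows, -1)


def segment_windows(
    rec: AccelRecording,
    window_s: float = 6.0,
    overlap: float = 0.5,
    remove_dc: bool = True,
    window_len: Optional[int] = None,
) -> WindowSet:
    """Cut maximal aligned windows; the trailing partial window is discarded.

    With ``remove_dc`` each axis of each window is mean-centred (this cancels
    the constant gravity component). ``window_len`` overrides ``window_s``
    when an exact sample count (e.g. 512) is required.
    """
    L = int(round(window_s * rec.fs)) if window_len is None else int(window_len)
    if rec.n_samples < L:
        raise ValueError("recording shorter than one window")
    hop = max(int(round(L * (1.0 - overlap))), 1)
    n_w = (rec.n_samples - L) // hop + 1
    starts = np.arange(n_w) * hop
    idx = starts[:, None] + np.arange(L)[None, :]
    win = rec.acc[idx]  # (W, L, 3)
    win = np.transpose(win, (0, 2, 1)).copy()  # (W, 3, L)
    if remove_dc:
        win -= win.mean(axis=2, keepdims=True)
    return WindowSet(
        windows=win, fs=rec.fs, window_s=L / rec.fs, overlap=overlap,
        starts=starts, recording_id=rec.subject_id,
    )


def label_windows(
    ws: WindowSet, mask: np.ndarray, rule_fraction: float = 0.5
) -> WindowSet:
    """Label a window gait iff the fraction of gait samples it covers is
    strictly greater than ``rule_fraction``."""
    if mask is None:
        raise ValueError("mask required to label windows")
    mask = np.asarray(mask)
    L = ws.window_len
    idx = ws.starts[:, None] + np.arange(L)[None, :]
    frac = mask[idx].mean(axis=1)
    labels = (frac > rule_fraction).astype(np.int8)
    return replace(ws, labels=labels)


def window_sample_masks(ws: WindowSet, mask: np.ndarray) -> np.ndarray:
    """(W, L) per-sample labels aligned with each window (for semantic
    segmentation training)."""
    idx = ws.starts[:, None] + np.arange(ws.window_len)[None, :]
    return np.asarray(mask)[idx]


def bandpower_features(windows: np.ndarray, fs: float, n_bands: int = 12,
                       eps: float = 1e-6) -> np.ndarray:
    """Log band-power feature vectors of DC-removed windows.

    Power spectra of each channel are summed across channels and pooled into
    ``n_bands`` equal-width bands over [0, Nyquist]; the log makes the
    features scale-comparable. Band powers are invariant to the time shift
    and phase of the quasi-periodic gait cycle, so windows of the same
    movement type cluster regardless of when the window cuts the cycle —
    the property the one-class density model needs to generalize across
    subjects.
    """
    windows = np.asarray(windows, dtype=float)
    mag2 = np.abs(np.fft.rfft(windows, axis=2)) ** 2
    tot = mag2.sum(axis=1)  # (W, n_freq) power summed over channels
    freqs = np.fft.rfftfreq(windows.shape[2], 1.0 / fs)
    edges = np.linspace(0.0, fs / 2.0, n_bands + 1)
    bands = []
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (freqs >= a) & ((freqs <= b) if i == n_bands - 1 else (freqs < b))
        bands.append(tot[:, sel].sum(axis=1))
    return np.log(np.stack(bands, axis=1) + eps)


@dataclass
class NormStats:
    """Per-feature mean/SD fitted on the training set only; zero-variance
    features are dropped with a warning."""

    mean: np.ndarray
    std: np.ndarray
    keep: np.ndarray  # boolean feature filter


def fit_norm_stats(train_features: np.ndarray, eps: float = 1e-12) -> NormStats:
    x = np.asarray(train_features, dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    keep = std > eps
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
    return NormStats(mean=mean, std=std, keep=keep)


def apply_norm(features: np.ndarray, stats: NormStats) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    z = (x[:, stats.keep] - stats.mean[stats.keep]) / stats.std[stats.keep]
    return z


def inverse_norm(z: np.ndarray, stats: NormStats) -> np.ndarray:
    return z * stats.std[stats.keep] + stats.mean[stats.keep]


@dataclass
class PCAProjection:
    """Orthonormal top-variance basis estimated from training data only."""

    components: np.ndarray  # (n_components, d)
    mean: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(train_features: np.ndarray, n_components=0.95) -> PCAProjection:
    """Fit PCA on training features; ``n_components`` may be an int or a
    variance fraction (default: smallest count explaining >= 95%)."""
    x = np.asarray(train_features, dtype=float)
    if isinstance(n_components, (int, np.integer)):
        if n_components > min(x.shape):
            raise ValueError("n_components exceeds feature rank")
    p = _SKPCA(n_components=n_components, svd_solver="full").fit(x)
    return PCAProjection(
        components=p.components_, mean=p.mean_,
        explained_variance=p.explained_variance_,
    )


def apply_pca(features: np.ndarray, proj: PCAProjection) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    return (x - proj.mean) @ proj.components.T


@dataclass
class FoldSplit:
    """Subject-disjoint k-fold assignment."""

    k: int
    assignment: dict[str, int]
    fold_gait_pct: Optional[dict[int, float]] = None

    def train_test_subjects(self, fold: int) -> tuple[list[str], list[str]]:
        test = sorted(s for s, f in self.assignment.items() if f == fold)
        train = sorted(s for s, f in self.assignment.items() if f != fold)
        return train, test


def make_folds(
    subject_ids: Sequence[str],
    k: int = 5,
    seed: int = 0,
    gait_pct: Optional[dict[str, float]] = None,
) -> FoldSplit:
    """Partition subjects into k disjoint folds.

    Without ``gait_pct`` the split is a seeded balanced random partition.
    With per-subject gait percentages, subjects are assigned greedily
    (largest first) to the fold whose running mean gait percentage is
    nearest the global mean, keeping fold gait fractions relatively
    balanced while equalizing fold sizes.
    """
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise ValueError("fewer subjects than folds")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    cap = int(np.ceil(len(subjects) / k))
    if gait_pct is None:
        order = rng.permutation(len(subjects))
        for i, j in enumerate(order):
            assignment[subjects[j]] = i % k
    else:
        order = sorted(subjects, key=lambda s: -gait_pct.get(s, 0.0))
        target = float(np.mean([gait_pct.get(s, 0.0) for s in subjects]))
        sums = np.zeros(k)
        counts = np.zeros(k, dtype=int)
        for s in order:
            open_folds = np.flatnonzero(counts < cap)
            means = np.where(
                counts[open_folds] > 0,
                sums[open_folds] / np.maximum(counts[open_folds], 1),
                target,
            )
            # prefer emptier folds on ties, deterministic ordering
            j = open_folds[np.lexsort((counts[open_folds], np.abs(means - target)))[0]]
            assignment[s] = int(j)
            sums[j] += gait_pct.get(s, 0.0)
            counts[j] += 1
    fold_pct = None
    if gait_pct is not None:
        fold_pct = {
            f: float(np.mean([gait_pct[s] for s, ff in assignment.items() if ff == f]))
            for f in range(k)
        }
    return FoldSplit(k=k, assignment=assignment, fold_gait_pct=fold_pct)
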