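"""Matplotlib helpers for detector curves and recordings."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import CurveResult
from .io import AccelRecording

__all__ = ["plot_curves", "plot_recording"]


def plot_curves(curves: dict[str, tuple[CurveResult, CurveResult]], path=None):
    """ROC (right) and PR (left) panels, one line per detector."""
    fig, (ax_pr, ax_roc) = plt.subplots(1, 2, figsize=(10, 4))
    for name, (roc, pr) in curves.items():
        ax_roc.plot(roc.x, roc.y, label=f"{name} (AUC {roc.auc:.2f})")
        ax_pr.plot(pr.x, pr.y, label=f"{name} (AUC {pr.auc:.2f})")
    ax_roc.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax_roc.set(xlabel="false positive rate", ylabel="true positive rate",
               title="ROC")
    ax_pr.set(xlabel="recall", ylabel="precision", title="Precision-recall")
    for ax in (ax_roc, ax_pr):
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_recording(rec: AccelRecording, start_s: float = 0.0,
                   duration_s: float = 120.0, path=None):
    """Acceleration norm with the gait mask shaded."""
    from .preprocessing import euclidean_norm

    s = int(start_s * rec.fs)
    e = min(int((start_s + duration_s) * rec.fs), rec.n_samples)
    t = np.arange(s, e) / rec.fs
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(t, euclidean_norm(rec.acc[s:e]), lw=0.5)
    if rec.mask is not None:
        m = rec.mask[s:e].astype(bool)
        ax.fill_between(t, 0, 1, where=m, transform=ax.get_xaxis_transform(),
                        alpha=0.2, color="tab:green", label="gait")
        ax.legend()
    ax.set(xlabel="time (s)", ylabel="|a| (m/s$^2$)",
           title=f"{rec.subject_id} ({rec.t0.date()})")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
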