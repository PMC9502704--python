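"""Common detector Model/Results contract.

Every detector is a model object constructed from (or fitted to) training
data whose ``fit()`` returns a results object. All results objects expose a
common prediction contract — a gait probability per evaluation unit
(window or sample) — so the evaluation suite can treat the five detectors
uniformly. The feature-based detector is the one exception: its output is a
hard binary decision, so its "probability" is 0/1 and it is excluded from
ROC/PR analyses.
"""

from __future__ import annotations

from typing import Optional

import numpy as np


class DetectorResults:
    """Base class for fitted-detector results."""

    #: "window" or "sample" — the native granularity of predict_proba
    granularity: str = "window"
    #: whether predict_proba returns a continuous score (ROC/PR applicable)
    continuous: bool = True

    def predict_proba(self, *args, **kwargs) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _summary_rows(self) -> list[tuple[str, object]]:
        return []

    def summary(self) -> str:
        rows = self._summary_rows()
        width = max((len(k) for k, _ in rows), default=10) + 2
        lines = [type(self).__name__, "=" * 40]
        for k, v in rows:
            lines.append(f"{k:<{width}}{v}")
        return "\n".join(lines)


def windows_to_samples(
    probs: np.ndarray,
    starts: np.ndarray,
    window_len: int,
    n_samples: int,
    kept_idx: Optional[np.ndarray] = None,
    fill: float = 0.0,
) -> np.ndarray:
    """Spread per-window probabilities back onto per-sample resolution by
    averaging the windows covering each sample.

    ``kept_idx`` maps (gated) signal positions back to original sample
    indices; samples covered by no window (including gate-removed ones)
    receive ``fill`` (non-gait).
    """
    acc = np.zeros(n_samples)
    cnt = np.zeros(n_samples)
    for p, s in zip(probs, starts):
        idx = np.arange(s, s + window_len)
        if kept_idx is not None:
            idx = kept_idx[idx]
        acc[idx] += p
        cnt[idx] += 1
    out = np.full(n_samples, fill, dtype=float)
    nz = cnt > 0
    out[nz] = acc[nz] / cnt[nz]
    return out
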