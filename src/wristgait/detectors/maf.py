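"""Unsupervised one-class gait detection with a masked autoregressive flow.

A masked autoregressive flow (MAF) stacks autoregressive affine layers
(MADE blocks). Each layer maps a feature vector x to a latent u by

    u_i = (x_i - mu_i(x_{<i})) * exp(-alpha_i(x_{<i})),

where the shift mu and log-scale alpha are produced by feed-forward
networks whose weights are masked so that output i only sees inputs that
precede it under the layer's ordering. Because the transform is triangular,
the log-absolute-Jacobian determinant of the data->latent map is simply
-sum_i alpha_i, and with a standard-Gaussian base density the exact
log-density follows from the change-of-variables formula:

    log p(x) = log N(u; 0, I) + sum_layers (-sum_i alpha_i).

Training maximizes the log-likelihood of windows from the designated
"normal" class (gait by default; the non-gait direction is also supported).
At inference, the anomaly score of a window is -log p(x): windows unlike
the training class receive low density, hence high scores. Scores are
mapped to gait probabilities through the empirical CDF of a held-out
calibration split so the global high-precision 0.9 threshold applies
uniformly across detectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .._autodiff import Tensor
from ..nn import Adam, ExponentialDecay, MaskedLinear
from .base import DetectorResults

__all__ = ["MADELayer", "MAFModel", "MAFTrainConfig", "MAFDetector",
           "MAFResults", "score_to_probability"]

LOG2PI = np.log(2.0 * np.pi)


def _made_masks(dim: int, hidden: Sequence[int], order: np.ndarray):
    """Connectivity masks for one MADE block.

    ``order[i]`` is the autoregressive rank (1..dim) of input i. Hidden-unit
    degrees cycle over 1..dim-1; a hidden unit of degree m may see inputs of
    degree <= m, and output i (degree order[i]) may see hidden units of
    degree < order[i], which enforces mu_i, alpha_i = f(x_{<i}).
    """
    degrees = [np.asarray(order)]
    for h in hidden:
        if dim > 1:
            degrees.append(1 + np.arange(h) % (dim - 1))
        else:
            degrees.append(np.zeros(h, dtype=int))
    masks = []
    for d_in, d_out in zip(degrees[:-1], degrees[1:]):
        masks.append((d_out[None, :] >= d_in[:, None]).astype(float))
    out_mask = (np.asarray(order)[None, :] > degrees[-1][:, None]).astype(float)
    return masks, out_mask


class MADELayer:
    """One autoregressive affine flow layer.

    The shift/log-scale heads are zero-initialized so a freshly built layer
    is exactly the identity (u = x, logdet = 0); training moves it away
    from there.
    """

    def __init__(self, dim: int, hidden: Sequence[int] = (64, 64),
                 order: Optional[np.ndarray] = None,
                 rng: Optional[np.random.Generator] = None):
        rng = np.random.default_rng(0) if rng is None else rng
        self.dim = dim
        self.order = np.arange(1, dim + 1) if order is None else np.asarray(order)
        masks, out_mask = _made_masks(dim, hidden, self.order)
        self.hidden_layers = [MaskedLinear(rng, m) for m in masks]
        self.mu_head = MaskedLinear(rng, out_mask, zero_init=True)
        self.alpha_head = MaskedLinear(rng, out_mask, zero_init=True)

    # -- network outputs ----------------------------------------------------
    def _nets(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for lay in self.hidden_layers:
            h = lay(h).relu()
        return self.mu_head(h), self.alpha_head(h)

    def transform(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Data -> latent. Returns (u, per-sample logdet of du/dx = -sum alpha)."""
        mu, alpha = self._nets(x)
        u = (x - mu) * (-alpha).exp()
        logdet = -alpha.sum(axis=1)
        return u, logdet

    def inverse(self, u: np.ndarray) -> np.ndarray:
        """Latent -> data, sequentially by autoregressive rank."""
        u = np.atleast_2d(np.asarray(u, dtype=float))
        x = np.zeros_like(u)
        for rank in np.argsort(self.order):  # fill in autoregressive order
            mu, alpha = self._nets(Tensor(x))
            x[:, rank] = u[:, rank] * np.exp(alpha.data[:, rank]) + mu.data[:, rank]
        return x

    def params(self) -> list[Tensor]:
        ps = []
        for lay in self.hidden_layers:
            ps += lay.params()
        return ps + self.mu_head.params() + self.alpha_head.params()

    def set_affine(self, mu: np.ndarray, log_scale: np.ndarray) -> None:
        """Pin the layer to a fixed elementwise affine map x -> (x-mu)/s
        (useful for closed-form checks)."""
        for lay in (self.mu_head, self.alpha_head):
            lay.w.data[:] = 0.0
        self.mu_head.b.data[:] = mu
        self.alpha_head.b.data[:] = log_scale


class MAFModel:
    """Stack of MADE layers with reversed orderings between layers and a
    standard-Gaussian base density."""

    def __init__(self, dim: int, n_layers: int = 5, hidden: Sequence[int] = (64, 64),
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.layers: list[MADELayer] = []
        order = np.arange(1, dim + 1)
        for k in range(n_layers):
            self.layers.append(MADELayer(dim, hidden, order=order, rng=rng))
            order = order[::-1].copy()

    def transform(self, x: Tensor) -> tuple[Tensor, Tensor]:
        u, logdet = x, None
        for lay in self.layers:
            u, ld = lay.transform(u)
            logdet = ld if logdet is None else logdet + ld
        return u, logdet

    def inverse(self, u: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(u)
        for lay in reversed(self.layers):
            x = lay.inverse(x)
        return x

    def _log_prob(self, x: Tensor) -> Tensor:
        u, logdet = self.transform(x)
        base = (u * u).sum(axis=1) * -0.5 - 0.5 * self.dim * LOG2PI
        return base + logdet

    def log_density(self, x: np.ndarray, batch: int = 4096) -> np.ndarray:
        """Exact log p(x) for an (n, dim) array, no gradients recorded.

        Far-out-of-distribution inputs can overflow the affine scales; such
        points are maximally anomalous and their log-density saturates at a
        large negative value instead of propagating non-finite numbers.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty(x.shape[0])
        with np.errstate(over="ignore", invalid="ignore"):
            for s in range(0, x.shape[0], batch):
                out[s : s + batch] = self._log_prob(Tensor(x[s : s + batch])).data
        out[~np.isfinite(out)] = -1e12
        return np.clip(out, -1e12, 1e12)

    def params(self) -> list[Tensor]:
        return [p for lay in self.layers for p in lay.params()]


@dataclass
class MAFTrainConfig:
    lr_init: float = 0.01
    lr_decay: float = 0.95
    l2: float = 0.001              # 0.01 for the oa/pd profiles, 0.001 for hya
    epochs: int = 100
    batch_size: int = 256
    normal_class: str = "gait"     # or "non_gait"
    val_fraction: float = 0.10     # 90/10 train/validation split of the normal class
    n_layers: int = 5
    hidden: tuple[int, ...] = (64, 64)
    patience: int = 10
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_init <= 0 or self.l2 < 0:
            raise ValueError("lr_init must be > 0 and l2 >= 0")
        if self.normal_class not in ("gait", "non_gait"):
            raise ValueError("normal_class must be 'gait' or 'non_gait'")


def score_to_probability(scores: np.ndarray, calibration: np.ndarray,
                         normal_class: str = "gait") -> np.ndarray:
    """Map anomaly scores to gait probabilities via the empirical CDF of
    calibration (validation) scores, with mid-rank tie handling.

    With a gait-trained model, low anomaly score means gait-like: the map is
    monotone non-increasing, sending scores below every calibration score to
    probability 1 and the calibration median to 0.5. With a non-gait-trained
    model the complement applies.
    """
    cal = np.sort(np.asarray(calibration, dtype=float))
    if cal.size == 0:
        raise ValueError("empty calibration set")
    s = np.asarray(scores, dtype=float)
    lo = np.searchsorted(cal, s, side="left")
    hi = np.searchsorted(cal, s, side="right")
    ecdf = (lo + 0.5 * (hi - lo)) / cal.size
    return 1.0 - ecdf if normal_class == "gait" else ecdf


class MAFDetector:
    """One-class density model of the designated normal class.

    Parameters
    ----------
    features : (n, d) array of preprocessed window feature vectors, all
        drawn from the normal class.
    cfg : training configuration.
    """

    def __init__(self, features: np.ndarray, cfg: Optional[MAFTrainConfig] = None):
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.cfg = cfg or MAFTrainConfig()

    def fit(self, verbose: bool = False) -> "MAFResults":
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        x = self.features
        n = x.shape[0]
        perm = rng.permutation(n)
        n_val = max(int(round(cfg.val_fraction * n)), 1)
        val, train = x[perm[:n_val]], x[perm[n_val:]]
        model = MAFModel(x.shape[1], cfg.n_layers, cfg.hidden, seed=cfg.seed)
        opt = Adam(model.params(), lr=cfg.lr_init, weight_decay=cfg.l2)
        sched = ExponentialDecay(cfg.lr_init, cfg.lr_decay)
        history = {"train_nll": [], "val_nll": [], "lr": []}
        best = (np.inf, None, -1)
        for epoch in range(cfg.epochs):
            opt.lr = sched(epoch)
            order = rng.permutation(train.shape[0])
            ep_loss, n_batches = 0.0, 0
            for s in range(0, train.shape[0], cfg.batch_size):
                xb = Tensor(train[order[s : s + cfg.batch_size]])
                loss = -model._log_prob(xb).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"flow training diverged (non-finite loss at epoch {epoch})"
                    )
                opt.zero_grad()
                loss.backward()
                _clip(model.params(), cfg.grad_clip)
                opt.step()
                ep_loss += float(loss.data)
                n_batches += 1
            val_nll = float(-model.log_density(val).mean())
            history["train_nll"].append(ep_loss / max(n_batches, 1))
            history["val_nll"].append(val_nll)
            history["lr"].append(opt.lr)
            if verbose:
                print(f"epoch {epoch:3d}  train NLL {history['train_nll'][-1]:.4f}"
                      f"  val NLL {val_nll:.4f}")
            if val_nll < best[0] - 1e-6:
                best = (val_nll, [p.data.copy() for p in model.params()], epoch)
            elif epoch - best[2] >= cfg.patience:
                break
        if best[1] is not None:
            for p, d in zip(model.params(), best[1]):
                p.data = d
        cal_scores = -model.log_density(val)
        return MAFResults(model=model, cfg=cfg, history=history,
                          calibration_scores=cal_scores, best_epoch=best[2])


def _clip(params, max_norm: float) -> None:
    total = np.sqrt(sum((p.grad**2).sum() for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


@dataclass
class MAFResults(DetectorResults):
    model: MAFModel
    cfg: MAFTrainConfig
    history: dict
    calibration_scores: np.ndarray
    best_epoch: int
    granularity: str = "window"
    continuous: bool = True

    def anomaly_score(self, x: np.ndarray) -> np.ndarray:
        """score = -log p(x); higher = more anomalous under the normal class."""
        return -self.model.log_density(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return score_to_probability(
            self.anomaly_score(x), self.calibration_scores, self.cfg.normal_class
        )

    def _summary_rows(self):
        return [
            ("normal class", self.cfg.normal_class),
            ("feature dim", self.model.dim),
            ("MADE layers", len(self.model.layers)),
            ("epochs run", len(self.history["train_nll"])),
            ("best epoch", self.best_epoch),
            ("final train NLL", round(self.history["train_nll"][-1], 4)),
            ("best val NLL", round(min(self.history["val_nll"]), 4)),
            ("l2", self.cfg.l2),
        ]
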