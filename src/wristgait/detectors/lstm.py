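"""Deep residual bidirectional LSTM window classifier.

Each 6 s window (3-axis sequence) is read by a stack of bidirectional LSTM
layers: every layer runs one recurrent pass forward in time and one
backward, and concatenates the two hidden sequences. From the second layer
on, identity skip connections are added across the cell outputs (residual
stacking), which eases optimization of the deeper stack. The window's gait
probability comes from a sigmoid readout of the concatenated final states
of both directions of the top layer. Training minimizes binary
cross-entropy per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .._autodiff import Tensor, concat
from ..nn import Adam, Parameter, dropout_mask, glorot, sigmoid_np
from .base import DetectorResults

__all__ = ["LSTMConfig", "LSTMDetector", "LSTMResults"]


@dataclass
class LSTMConfig:
    layers: int = 2
    hidden: int = 64            # units per direction
    residual: bool = True
    bidirectional: bool = True
    dropout: float = 0.2
    lr: float = 1e-3
    epochs: int = 10
    batch_size: int = 64
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers < 1 or self.hidden < 1:
            raise ValueError("layers and hidden must be >= 1")


class _LSTMDirection:
    """One direction of one layer."""

    def __init__(self, rng, d_in: int, hidden: int):
        self.wx = Parameter(glorot(rng, d_in, 4 * hidden))
        self.wh = Parameter(glorot(rng, hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Parameter(b)
        self.hidden = hidden

    def run(self, xs: list[Tensor], reverse: bool) -> list[Tensor]:
        """xs: list over time of (B, d_in); returns hidden states per step
        in original time order."""
        H = self.hidden
        B = xs[0].shape[0]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: list[Tensor] = [None] * len(xs)
        for t in order:
            gates = xs[t] @ self.wx + h @ self.wh + self.b
            i = gates[:, 0 * H : 1 * H].sigmoid()
            f = gates[:, 1 * H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out[t] = h
        return out

    def params(self):
        return [self.wx, self.wh, self.b]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())


class _BiLSTMStack:
    def __init__(self, cfg: LSTMConfig, d_in: int, rng: np.random.Generator):
        self.cfg = cfg
        self.dirs: list[list[_LSTMDirection]] = []
        dims = []
        d = d_in
        width = cfg.hidden * (2 if cfg.bidirectional else 1)
        for layer in range(cfg.layers):
            fwd = _LSTMDirection(rng, d, cfg.hidden)
            if cfg.bidirectional:
                self.dirs.append([fwd, _LSTMDirection(rng, d, cfg.hidden)])
            else:
                self.dirs.append([fwd])
            dims.append(d)
            d = width
        self.out_w = Parameter(glorot(rng, width, 1))
        self.out_b = Parameter(np.zeros(1))
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> Tensor:
        """x: (B, 3, L) -> (B,) window logits."""
        B, F, L = x.shape
        xs = [Tensor(x[:, :, t]) for t in range(L)]
        for li, layer in enumerate(self.dirs):
            outs = layer[0].run(xs, reverse=False)
            if len(layer) == 2:
                back = layer[1].run(xs, reverse=True)
                seq = [concat([a, b], axis=1) for a, b in zip(outs, back)]
                finals = [outs[-1], back[0]]
            else:
                seq = outs
                finals = [outs[-1]]
            if self.cfg.residual and li > 0:  # identity skip across cell outputs
                seq = [s + xin for s, xin in zip(seq, xs)]
            if training and self.cfg.dropout > 0 and li < len(self.dirs) - 1:
                m = dropout_mask(self.rng, seq[0].shape, self.cfg.dropout)
                seq = [s * m for s in seq]
            xs = seq
            last_finals = finals
        pooled = concat(last_finals, axis=1) if len(last_finals) > 1 else last_finals[0]
        logit = pooled @ self.out_w + self.out_b
        return logit.reshape(-1)

    def params(self):
        ps = []
        for layer in self.dirs:
            for d in layer:
                ps += d.params()
        return ps + [self.out_w, self.out_b]

    def layer_parameter_counts(self) -> list[int]:
        """Recurrent parameter count of each layer's directional stack."""
        return [sum(d.n_parameters() for d in layer) for layer in self.dirs]


def _bce(logits: Tensor, y: np.ndarray) -> Tensor:
    ax = logits * (logits.data > 0) * 2 - logits  # |x|
    sp = logits.relu() + (1.0 + (-ax).exp()).log()
    loss = sp - logits * y
    return loss.sum() * (1.0 / loss.data.size)


class LSTMDetector:
    """Model object over labelled fixed-width windows.

    Parameters
    ----------
    windows : (W, 3, L) DC-removed windows (6 s default).
    labels : (W,) binary window labels.
    """

    def __init__(self, windows: np.ndarray, labels: np.ndarray,
                 cfg: Optional[LSTMConfig] = None):
        self.windows = np.asarray(windows, dtype=float)
        self.labels = np.asarray(labels, dtype=float)
        if self.windows.shape[0] != self.labels.shape[0]:
            raise ValueError("windows/labels mismatch")
        if self.labels.min() == self.labels.max():
            raise ValueError("training data contain a single class")
        self.cfg = cfg or LSTMConfig()

    def fit(self, verbose: bool = False) -> "LSTMResults":
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        # per-axis standardization fitted on the training windows
        mu = self.windows.mean(axis=(0, 2), keepdims=True)
        sd = self.windows.std(axis=(0, 2), keepdims=True) + 1e-9
        xs = (self.windows - mu) / sd
        net = _BiLSTMStack(cfg, d_in=xs.shape[1], rng=rng)
        opt = Adam(net.params(), lr=cfg.lr)
        n = xs.shape[0]
        perm = rng.permutation(n)
        n_val = max(int(round(cfg.val_fraction * n)), 1)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        history = {"train_loss": [], "val_loss": []}
        best = (np.inf, None)
        for epoch in range(cfg.epochs):
            order = rng.permutation(tr_idx)
            ep, nb = 0.0, 0
            for s in range(0, order.size, cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                logits = net.forward(xs[idx], training=True)
                loss = _bce(logits, self.labels[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"training diverged at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep += float(loss.data)
                nb += 1
            vl = float(_bce(net.forward(xs[val_idx], training=False),
                            self.labels[val_idx]).data)
            history["train_loss"].append(ep / max(nb, 1))
            history["val_loss"].append(vl)
            if verbose:
                print(f"epoch {epoch:3d}  train {history['train_loss'][-1]:.4f}"
                      f"  val {vl:.4f}")
            if vl < best[0]:
                best = (vl, [p.data.copy() for p in net.params()])
        if best[1] is not None:
            for p, d in zip(net.params(), best[1]):
                p.data = d
        return LSTMResults(net=net, cfg=cfg, history=history,
                           norm_mu=mu, norm_sd=sd)


@dataclass
class LSTMResults(DetectorResults):
    net: _BiLSTMStack = None
    cfg: LSTMConfig = None
    history: dict = field(default_factory=dict)
    norm_mu: np.ndarray = None
    norm_sd: np.ndarray = None
    granularity: str = "window"
    continuous: bool = True

    def predict_windows(self, windows: np.ndarray, batch: int = 256) -> np.ndarray:
        """(W, 3, L) -> (W,) gait probabilities, ordered as given."""
        windows = np.asarray(windows, dtype=float)
        xs = (windows - self.norm_mu) / self.norm_sd
        out = np.empty(xs.shape[0])
        for s in range(0, xs.shape[0], batch):
            logits = self.net.forward(xs[s : s + batch], training=False)
            out[s : s + batch] = sigmoid_np(logits.data)
        return out

    predict_proba = predict_windows

    def _summary_rows(self):
        return [
            ("layers", self.cfg.layers),
            ("hidden/direction", self.cfg.hidden),
            ("bidirectional", self.cfg.bidirectional),
            ("residual", self.cfg.residual),
            ("parameters", sum(p.data.size for p in self.net.params())),
            ("epochs", len(self.history.get("train_loss", []))),
            ("best val loss", round(min(self.history["val_loss"]), 4)
             if self.history.get("val_loss") else None),
        ]
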