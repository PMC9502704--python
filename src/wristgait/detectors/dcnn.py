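"""Semantic-segmentation convolutional network for per-sample gait labels.

A U-Net-style encoder/decoder over 3 x 512 accelerometer windows: the three
axes enter as input channels of a 1-D signal, kernels span time only, and
the time axis is halved at each encoder level while channels double; the
decoder mirrors the encoder with nearest-neighbour upsampling and skip
concatenation. A final 1x1 convolution produces one per-time-step gait
logit, so every sample of the window receives its own probability. Batch
normalization stabilizes training; dropout regularizes the bottleneck.
Training minimizes per-time-step binary cross-entropy with optional
positive-class weighting for the gait/non-gait imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .._autodiff import Tensor, concat, conv1d, maxpool1d, upsample1d
from ..io import AccelRecording
from ..nn import Adam, BatchNorm, Parameter, dropout_mask, glorot
from .base import DetectorResults

__all__ = ["DCNNConfig", "DCNNDetector", "DCNNResults"]


@dataclass
class DCNNConfig:
    window_len: int = 512
    depth: int = 4
    base_channels: int = 16
    kernel: int = 5
    dropout: float = 0.2
    batchnorm: bool = True
    batch_size: int = 64
    lr: float = 1e-3
    epochs: int = 10
    pos_weight: float = 1.0
    val_fraction: float = 0.15
    overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len % (2**self.depth):
            raise ValueError("window_len must be divisible by 2^depth")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


class _ConvBlock:
    def __init__(self, rng, c_in, c_out, kernel, batchnorm):
        fan = c_in * kernel
        self.w = Parameter(glorot(rng, fan, c_out * kernel,
                                  shape=(c_out, c_in, kernel)))
        self.b = Parameter(np.zeros(c_out))
        self.bn = BatchNorm(c_out) if batchnorm else None
        self.pad = kernel // 2

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = conv1d(x, self.w, self.b, pad=self.pad)
        if self.bn is not None:
            h = self.bn(h, training)
        return h.relu()

    def params(self):
        ps = [self.w, self.b]
        if self.bn is not None:
            ps += self.bn.params()
        return ps


class _UNet1D:
    """Encoder-decoder over (batch, channels, time); the 3 axes are the
    input channels."""

    def __init__(self, cfg: DCNNConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = [cfg.base_channels * 2**i for i in range(cfg.depth + 1)]
        self.enc = [
            _ConvBlock(rng, 3 if i == 0 else ch[i - 1], ch[i], cfg.kernel,
                       cfg.batchnorm)
            for i in range(cfg.depth)
        ]
        self.bottleneck = _ConvBlock(rng, ch[cfg.depth - 1], ch[cfg.depth],
                                     cfg.kernel, cfg.batchnorm)
        self.dec = [
            _ConvBlock(rng, ch[i + 1] + ch[i], ch[i], cfg.kernel, cfg.batchnorm)
            for i in reversed(range(cfg.depth))
        ]
        self.head_w = Parameter(glorot(rng, ch[0], 1, shape=(1, ch[0], 1)))
        self.head_b = Parameter(np.zeros(1))
        self.rng = rng

    def logits(self, x: np.ndarray, training: bool) -> Tensor:
        """x: (B, 3, T) -> per-sample logits (B, T)."""
        B, R, T = x.shape
        h = Tensor(x)
        skips = []
        for blk in self.enc:
            h = blk(h, training)
            skips.append(h)
            h = maxpool1d(h, 2)
        h = self.bottleneck(h, training)
        if training and self.cfg.dropout > 0:
            h = h * dropout_mask(self.rng, h.shape, self.cfg.dropout)
        for blk, skip in zip(self.dec, reversed(skips)):
            h = upsample1d(h, 2)
            h = concat([h, skip], axis=1)
            h = blk(h, training)
        out = conv1d(h, self.head_w, self.head_b, pad=0)
        return out.reshape(B, T)

    def params(self):
        ps = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            ps += blk.params()
        return ps + [self.head_w, self.head_b]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))


def _bce_from_logits(logits: Tensor, y: np.ndarray, pos_weight: float) -> Tensor:
    """Numerically safe binary cross-entropy: softplus form."""
    # softplus(x) = max(x,0) + log(1+exp(-|x|))
    ax = (logits * (logits.data > 0) * 2 - logits)  # |x| via sign trick
    sp = logits.relu() + (1.0 + (-ax).exp()).log()
    w = np.where(y > 0.5, pos_weight, 1.0)
    loss = (sp - logits * y) * w
    return loss.sum() * (1.0 / loss.data.size)


class DCNNDetector:
    """Model object over labelled 512-sample windows.

    Parameters
    ----------
    windows : (W, 3, 512) DC-removed training windows.
    sample_labels : (W, 512) per-sample binary gait labels.
    """

    def __init__(self, windows: np.ndarray, sample_labels: np.ndarray,
                 cfg: Optional[DCNNConfig] = None):
        self.windows = np.asarray(windows, dtype=float)
        self.labels = np.asarray(sample_labels, dtype=float)
        if self.windows.shape[0] != self.labels.shape[0]:
            raise ValueError("windows/labels mismatch")
        if self.labels.sum() == 0 or (1 - self.labels).sum() == 0:
            raise ValueError("training data contain a single class")
        self.cfg = cfg or DCNNConfig()

    def fit(self, verbose: bool = False) -> "DCNNResults":
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        net = _UNet1D(cfg, rng)
        opt = Adam(net.params(), lr=cfg.lr)
        # per-axis standardization fitted on the training windows
        mu = self.windows.mean(axis=(0, 2), keepdims=True)
        sd = self.windows.std(axis=(0, 2), keepdims=True) + 1e-9
        self.windows = (self.windows - mu) / sd
        n = self.windows.shape[0]
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
                logits = net.logits(self.windows[idx], training=True)
                loss = _bce_from_logits(logits, self.labels[idx], cfg.pos_weight)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"training diverged at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep += float(loss.data)
                nb += 1
            vl = self._eval_loss(net, val_idx)
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
        return DCNNResults(net=net, cfg=cfg, history=history,
                           n_parameters=net.n_parameters(),
                           norm_mu=mu, norm_sd=sd)

    def _eval_loss(self, net, idx) -> float:
        logits = net.logits(self.windows[idx], training=False)
        return float(_bce_from_logits(logits, self.labels[idx],
                                      self.cfg.pos_weight).data)


@dataclass
class DCNNResults(DetectorResults):
    net: _UNet1D = None
    cfg: DCNNConfig = None
    history: dict = field(default_factory=dict)
    n_parameters: int = 0
    norm_mu: np.ndarray = None
    norm_sd: np.ndarray = None
    granularity: str = "sample"
    continuous: bool = True

    def predict_window_probs(self, windows: np.ndarray,
                             batch: int = 64) -> np.ndarray:
        """(W, 3, 512) -> (W, 512) per-sample probabilities."""
        windows = np.asarray(windows, dtype=float)
        if self.norm_mu is not None:
            windows = (windows - self.norm_mu) / self.norm_sd
        out = np.empty((windows.shape[0], windows.shape[2]))
        for s in range(0, windows.shape[0], batch):
            logits = self.net.logits(windows[s : s + batch], training=False)
            out[s : s + batch] = 1.0 / (1.0 + np.exp(-np.clip(logits.data, -60, 60)))
        return out

    def predict_samples(self, rec: AccelRecording) -> np.ndarray:
        """Per-sample gait probability for a whole recording.

        The recording is cut into 512-sample windows at the configured
        overlap (plus a final right-aligned window covering the tail);
        overlapping outputs are merged by averaging per sample.
        """
        L = self.cfg.window_len
        if rec.n_samples < L:
            raise ValueError("recording shorter than one 512-sample window")
        hop = max(int(round(L * (1 - self.cfg.overlap))), 1)
        starts = list(range(0, rec.n_samples - L + 1, hop))
        if starts[-1] + L < rec.n_samples:
            starts.append(rec.n_samples - L)
        wins = np.stack([rec.acc[s : s + L].T for s in starts])
        wins = wins - wins.mean(axis=2, keepdims=True)
        probs = self.predict_window_probs(wins)
        acc = np.zeros(rec.n_samples)
        cnt = np.zeros(rec.n_samples)
        for p, s in zip(probs, starts):
            acc[s : s + L] += p
            cnt[s : s + L] += 1
        return acc / np.maximum(cnt, 1)

    def _summary_rows(self):
        return [
            ("depth", self.cfg.depth),
            ("base channels", self.cfg.base_channels),
            ("parameters", self.n_parameters),
            ("epochs", len(self.history.get("train_loss", []))),
            ("final train loss", round(self.history["train_loss"][-1], 4)
             if self.history.get("train_loss") else None),
            ("best val loss", round(min(self.history["val_loss"]), 4)
             if self.history.get("val_loss") else None),
        ]
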