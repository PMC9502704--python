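"""Neural-network building blocks on top of the autodiff engine.

Layers keep their weights as ``Tensor`` leaves with ``requires_grad=True``;
the :class:`Adam` optimizer updates them in place. Weight initialization is
seeded Glorot-uniform, so training is reproducible for a fixed seed and
batch order.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._autodiff import Tensor

__all__ = ["Parameter", "glorot", "Linear", "MaskedLinear", "BatchNorm", "Adam",
           "dropout_mask", "ExponentialDecay", "sigmoid_np"]


def sigmoid_np(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out) if shape is None else shape)


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 zero_init: bool = False):
        w = np.zeros((d_in, d_out)) if zero_init else glorot(rng, d_in, d_out)
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class MaskedLinear:
    """Linear layer with a fixed binary connectivity mask (for autoregressive
    networks): out_j depends only on in_i with mask[i, j] == 1."""

    def __init__(self, rng: np.random.Generator, mask: np.ndarray,
                 zero_init: bool = False):
        d_in, d_out = mask.shape
        w = np.zeros((d_in, d_out)) if zero_init else glorot(rng, d_in, d_out)
        self.w = Parameter(w * mask)
        self.b = Parameter(np.zeros(d_out))
        self.mask = Tensor(mask.astype(float))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ (self.w * self.mask) + self.b

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class BatchNorm:
    """Batch normalization over (N, C, T) activations, per channel."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True).mean(axis=2, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True).mean(axis=2, keepdims=True)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mu.data[0, :, 0])
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var.data[0, :, 0])
            xhat = xc * (var + self.eps) ** -0.5
        else:
            mu = self.run_mean[None, :, None]
            sd = np.sqrt(self.run_var + self.eps)[None, :, None]
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]


def dropout_mask(rng: np.random.Generator, shape, rate: float) -> Tensor:
    """Inverted-dropout multiplier (training time only)."""
    keep = 1.0 - rate
    return Tensor((rng.random(shape) < keep) / keep)


class ExponentialDecay:
    """lr(epoch) = lr0 * rate^epoch."""

    def __init__(self, lr0: float, rate: float = 0.95):
        self.lr0 = lr0
        self.rate = rate

    def __call__(self, epoch: int) -> float:
        return self.lr0 * self.rate**epoch


class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
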