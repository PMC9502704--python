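"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the neural detectors need: broadcasted
arithmetic, 2-D matmul, elementwise nonlinearities, reductions, reshaping,
slicing, concatenation, and 1-D convolution/pooling/upsampling primitives.
Gradients are accumulated by a topological-order sweep over the recorded
tape. Arrays are float64 throughout; determinism follows from seeded
initializers and a fixed batch order.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d", "upsample1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )
        self._parents: tuple = tuple(parents) if self.requires_grad else ()

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- autograd --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: tapes can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf parameter / input
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, fn in node._parents:
                if not p.requires_grad:
                    continue
                pg = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = Tensor.as_tensor(other)
        return Tensor(
            self.data + o.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (o, lambda g: _unbroadcast(g, o.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        o = Tensor.as_tensor(other)
        return Tensor(
            self.data * o.data,
            parents=(
                (self, lambda g: _unbroadcast(g * o.data, self.data.shape)),
                (o, lambda g: _unbroadcast(g * self.data, o.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor.as_tensor(other)
        return Tensor(
            self.data / o.data,
            parents=(
                (self, lambda g: _unbroadcast(g / o.data, self.data.shape)),
                (o, lambda g: _unbroadcast(-g * self.data / o.data**2, o.data.shape)),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, k: float):
        return Tensor(
            self.data**k,
            parents=((self, lambda g: g * k * self.data ** (k - 1)),),
        )

    def __matmul__(self, other):
        o = Tensor.as_tensor(other)
        if self.data.ndim != 2 or o.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        return Tensor(
            self.data @ o.data,
            parents=(
                (self, lambda g: g @ o.data.T),
                (o, lambda g: self.data.T @ g),
            ),
        )

    # ---- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=((self, lambda g: g * out),))

    def log(self):
        return Tensor(np.log(self.data), parents=((self, lambda g: g / self.data),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, parents=((self, lambda g: g * (1.0 - out**2)),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor(out, parents=((self, lambda g: g * out * (1.0 - out)),))

    def relu(self):
        keep = self.data > 0
        return Tensor(
            np.where(keep, self.data, 0.0), parents=((self, lambda g: g * keep),)
        )

    # ---- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(out, parents=((self, back),))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(
            self.data.reshape(*shape),
            parents=((self, lambda g: g.reshape(old)),),
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            parents=((self, lambda g: g.transpose(inv)),),
        )

    def __getitem__(self, key):
        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return out

        return Tensor(self.data[key], parents=((self, back),))


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_back(i):
        sl = [slice(None)] * tensors[i].data.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        return lambda g: g[tuple(sl)]

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple((t, make_back(i)) for i, t in enumerate(tensors)),
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 0) -> Tensor:
    """'Same'-style 1-D convolution (cross-correlation): x (N, C, T),
    w (O, C, K), output (N, O, T + 2*pad - K + 1). Computed as a short loop
    over the K kernel taps with batched matmuls, which avoids materializing
    im2col patch copies."""
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad)))
    N, C, Tp = xd.shape
    O, _, K = w.data.shape
    To = Tp - K + 1
    out = np.zeros((N, O, To))
    for k in range(K):
        out += np.matmul(w.data[None, :, :, k], xd[:, :, k : k + To])
    if b is not None:
        out += b.data[None, :, None]

    def back_x(g):
        dxp = np.zeros((N, C, Tp))
        for k in range(K):
            dxp[:, :, k : k + To] += np.matmul(w.data[None, :, :, k].transpose(0, 2, 1), g)
        return dxp[:, :, pad : Tp - pad] if pad else dxp

    def back_w(g):
        dw = np.empty((O, C, K))
        for k in range(K):
            dw[:, :, k] = np.matmul(
                g, xd[:, :, k : k + To].transpose(0, 2, 1)
            ).sum(axis=0)
        return dw

    parents = [(x, back_x), (w, back_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2))))
    return Tensor(out, parents=tuple(parents))


def maxpool1d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling along the last axis (length divisible)."""
    n, c, t = x.data.shape
    if t % factor:
        raise ValueError("length not divisible by pooling factor")
    r = x.data.reshape(n, c, t // factor, factor)
    arg = r.argmax(axis=3)
    out = np.take_along_axis(r, arg[..., None], axis=3)[..., 0]

    def back(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=3)
        return gr.reshape(n, c, t)

    return Tensor(out, parents=((x, back),))


def upsample1d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour repetition along the last axis."""
    out = np.repeat(x.data, factor, axis=-1)
    n, c, t = x.data.shape

    def back(g):
        return g.reshape(n, c, t, factor).sum(axis=3)

    return Tensor(out, parents=((x, back),))
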