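"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine exists so the transformer can be trained on CPU with plain
numpy: a :class:`Tensor` wraps a float32 ndarray and records, for every
operation whose inputs require gradients, a closure that accumulates the
chain-rule contribution into its parents.  When no input requires a
gradient the op degrades to a bare numpy call, so inference builds no
graph.

Only the primitives the model needs are provided: broadcasting add/mul,
(batched) matmul, elementwise exp/log/erf/power, reductions, reshape /
transpose / slicing / concatenation, and a numerically stable softmax and
log-softmax built from them.  An AdamW optimizer with decoupled weight
decay lives at the bottom.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concat", "softmax", "log_softmax", "gelu", "layer_norm",
           "AdamW", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A float32 ndarray with an optional autodiff tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    grad_enabled: bool = True  # class-wide switch, see no_grad()

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if Tensor.grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (any-shape) tensor with seed gradient 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep at 12 blocks
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._node(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def backward(g):
            a._accumulate(-g)

        return self._node(-self.data, (a,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._node(self.data * other.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        a = self
        out_data = self.data ** np.float32(exponent)

        def backward(g):
            a._accumulate(g * np.float32(exponent) * self.data ** np.float32(exponent - 1.0))

        return self._node(out_data, (a,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        a, b = self, other
        out_data = self.data @ other.data

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return self._node(out_data, (a, b), backward)

    # ------------------------------------------------------------ elementwise

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(self.data)

        def backward(g):
            a._accumulate(g * out_data)

        return self._node(out_data, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return self._node(np.log(self.data), (a,), backward)

    def erf(self) -> "Tensor":
        a = self
        out_data = _erf(self.data).astype(np.float32)

        def backward(g):
            a._accumulate(g * (2.0 / math.sqrt(math.pi)) * np.exp(-a.data ** 2))

        return self._node(out_data, (a,), backward)

    # -------------------------------------------------------------- reshaping

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old_shape = self.shape

        def backward(g):
            a._accumulate(g.reshape(old_shape))

        return self._node(self.data.reshape(shape), (a,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g):
            a._accumulate(g.transpose(inv))

        return self._node(self.data.transpose(axes), (a,), backward)

    def swap_last(self) -> "Tensor":
        """Swap the two trailing axes (used for K^T in attention)."""
        axes = list(range(self.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return self.transpose(axes)

    def broadcast_to(self, shape: Sequence[int]) -> "Tensor":
        a = self
        shape = tuple(shape)

        def backward(g):
            a._accumulate(_unbroadcast(g, a.shape))

        return self._node(np.broadcast_to(self.data, shape).copy(), (a,), backward)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accumulate(full)

        return self._node(self.data[idx], (a,), backward)

    # -------------------------------------------------------------- reductions

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return self._node(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


class no_grad:
    """Context manager: ops inside build no graph (cheap inference)."""

    def __enter__(self):
        self._prev = Tensor.grad_enabled
        Tensor.grad_enabled = False

    def __exit__(self, *exc):
        Tensor.grad_enabled = self._prev


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._node(out_data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # The max shift is a constant w.r.t. the graph; its gradient cancels.
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    return x * 0.5 * ((x * (1.0 / math.sqrt(2.0))).erf() + 1.0)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gamma + beta


class AdamW:
    """AdamW with decoupled weight decay (no decay on 1-D tensors)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.05):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.data.ndim > 1:
                update = update + self.weight_decay * p.data
            p.data -= np.float32(self.lr) * update.astype(np.float32)
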