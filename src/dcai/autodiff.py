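"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; calling :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients.  Only the primitives needed by
the nodule classifier are implemented: broadcasting arithmetic, batched
matmul, reshape/transpose/concat, ReLU/GELU, row softmax, layer
normalization, reductions, and a fused softmax cross-entropy.

All data is kept in float64.  Gradient formulas for the fused primitives
(softmax, layer norm, cross-entropy) are the standard closed forms; everything
else follows from the chain rule plus an un-broadcast step that sums the
upstream gradient over axes the forward pass broadcast.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (evaluation mode) within the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                _accum(self, _unbroadcast(g, self.data.shape))
            if other.requires_grad:
                _accum(other, _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            _accum(self, -g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                _accum(self, _unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                _accum(self, _unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                _accum(other, _unbroadcast(-g * self.data / other.data ** 2,
                                           other.data.shape))

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        # batched-input x 2D-weight is the hot path; collapsing the batch
        # axes turns it into a single BLAS gemm call
        collapse = a.ndim > 2 and b.ndim == 2
        if collapse:
            out_data = (a.reshape(-1, a.shape[-1]) @ b).reshape(
                *a.shape[:-1], b.shape[1])
        else:
            out_data = a @ b

        def backward(g):
            if collapse:
                g2 = g.reshape(-1, g.shape[-1])
                if self.requires_grad:
                    _accum(self, (g2 @ b.T).reshape(a.shape))
                if other.requires_grad:
                    _accum(other, a.reshape(-1, a.shape[-1]).T @ g2)
                return
            if self.requires_grad:
                if a.ndim == 1 and b.ndim > 1:
                    ga = g @ np.swapaxes(b, -1, -2)
                elif b.ndim == 1:
                    ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                _accum(self, _unbroadcast(ga, a.shape))
            if other.requires_grad:
                if b.ndim == 1:
                    gb = a.T @ g if a.ndim > 1 else a * g
                elif a.ndim == 1:
                    gb = np.outer(a, g)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                _accum(other, _unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            _accum(self, g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            _accum(self, g.transpose(inv))

        return self._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, self.data.shape)
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                grad = np.broadcast_to(g, self.data.shape)
            _accum(self, grad.copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- activations ---------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            _accum(self, g * mask)

        return self._make(out_data, (self,), backward)

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = x * phi

        def backward(g):
            pdf = np.exp(-0.5 * x ** 2) / np.sqrt(2.0 * np.pi)
            _accum(self, g * (phi + x * pdf))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            _accum(self, g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            _accum(self, g / self.data)

        return self._make(out_data, (self,), backward)

    # -- backward driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(np.float64, copy=True)
    else:
        t.grad += g


# ---------------------------------------------------------------------------
# fused primitives
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(x, y * (g - dot))

    return x._make(y, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned affine."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data
    d = x.data.shape[-1]

    def backward(g):
        _accum(gamma, _unbroadcast(g * xhat, gamma.data.shape))
        _accum(beta, _unbroadcast(g, beta.data.shape))
        dxhat = g * gamma.data
        gx = inv * (dxhat
                    - dxhat.mean(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True) / d)
        _accum(x, gx)

    return x._make(out_data, (x, gamma, beta), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    ref = tensors[0]
    return ref._make(out_data, tuple(tensors), backward)


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices (B,)."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax[..., 0] + np.log(np.exp(z - zmax).sum(axis=-1))
    b = np.arange(z.shape[0])
    losses = lse - z[b, labels]
    out_data = np.array(losses.mean())

    def backward(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=-1, keepdims=True)
        p[b, labels] -= 1.0
        _accum(logits, g * p / z.shape[0])

    return logits._make(out_data, (logits,), backward)
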