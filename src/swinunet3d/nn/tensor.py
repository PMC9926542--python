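"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: just the operations the
shifted-window U-Net needs (broadcast arithmetic, batched matmul, axis
permutations, softmax, layer normalisation, GELU/PReLU/sigmoid, cyclic and
zero-filled spatial shifts, and an embedding-style gather for relative
position bias tables).  Everything is float32.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True

_INV_SQRT2 = np.float32(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


@contextmanager
def no_grad():
    """Disable graph construction (inference / data plumbing)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional backward closure on the tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "no_decay")

    # make numpy defer mixed expressions (ndarray op Tensor) to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.no_decay = False

    # ---- bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / float(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(_as_tensor(other), self)

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), pow_(self, -1.0))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(p for p in parents)
        out._backward = backward
    return out


# ---- primitive ops ---------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def pow_(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** exponent

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    out_data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))

    return _make(out_data, (a,), backward)


def mean_(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    return sum_(a, axis=axis, keepdims=keepdims) * (1.0 / count)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def gelu(a) -> Tensor:
    """Exact GELU x·Φ(x) with the Gaussian CDF via erf."""
    a = _as_tensor(a)
    cdf = 0.5 * (1.0 + erf(a.data * _INV_SQRT2))
    out_data = (a.data * cdf).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
            a._accumulate(g * (cdf + a.data * pdf))

    return _make(out_data, (a,), backward)


def prelu(a, slope: Tensor) -> Tensor:
    """Parametric rectifier; ``slope`` broadcasts against the channel axis."""
    a, slope = _as_tensor(a), _as_tensor(slope)
    neg = a.data < 0
    out_data = np.where(neg, slope.data * a.data, a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.where(neg, np.broadcast_to(slope.data, a.shape), 1.0) * g)
        if slope.requires_grad:
            slope._accumulate(_unbroadcast(np.where(neg, a.data, 0.0) * g, slope.shape))

    return _make(out_data, (a, slope), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            inner = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - inner))

    return _make(out_data, (a,), backward)


def layer_norm(a, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-token normalisation over the trailing (channel) axis."""
    a = _as_tensor(a)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv_std
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if a.requires_grad:
            gx = g * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(inv_std * (gx - m1 - xhat * m2))

    return _make(out_data, (a, gamma, beta), backward)


def roll(a, shifts: tuple[int, ...], axes: tuple[int, ...]) -> Tensor:
    a = _as_tensor(a)
    out_data = np.roll(a.data, shifts, axis=axes)
    inv = tuple(-s for s in shifts)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.roll(g, inv, axis=axes))

    return _make(out_data, (a,), backward)


def _shift_zero_np(arr: np.ndarray, offsets, axes) -> np.ndarray:
    """Shift with zero fill (no wrap-around), used by depthwise convolution."""
    out = arr
    for off, ax in zip(offsets, axes):
        if off == 0:
            continue
        shifted = np.zeros_like(out)
        src = [slice(None)] * out.ndim
        dst = [slice(None)] * out.ndim
        if off > 0:
            dst[ax] = slice(off, None)
            src[ax] = slice(None, -off)
        else:
            dst[ax] = slice(None, off)
            src[ax] = slice(-off, None)
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    return out


def shift_zero(a, offsets: tuple[int, ...], axes: tuple[int, ...]) -> Tensor:
    a = _as_tensor(a)
    out_data = _shift_zero_np(a.data, offsets, axes)
    inv = tuple(-o for o in offsets)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_shift_zero_np(g, inv, axes))

    return _make(out_data, (a,), backward)


def take_index(a: Tensor, i: int, axis: int = 0) -> Tensor:
    """Select slice ``i`` along ``axis`` (gradient scatters back into it)."""
    out_data = np.take(a.data, i, axis=axis)

    def backward(g):
        if a.requires_grad:
            da = np.zeros_like(a.data)
            sl = [slice(None)] * a.data.ndim
            sl[axis] = i
            da[tuple(sl)] = g
            a._accumulate(da)

    return _make(out_data, (a,), backward)


def index_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Gather ``table[:, idx]`` for a 2D table [rows, L]; backward scatter-adds.

    Used to expand a relative-position-bias table [heads, L] into per-pair
    biases [heads, T, T] given an integer offset-index matrix [T, T].
    """
    idx = np.asarray(idx)
    out_data = table.data[:, idx]

    def backward(g):
        if table.requires_grad:
            dt = np.zeros_like(table.data)
            rows = np.arange(table.shape[0])[:, None]
            np.add.at(dt, (rows, idx.reshape(1, -1)), g.reshape(table.shape[0], -1))
            table._accumulate(dt)

    return _make(out_data, (table,), backward)
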