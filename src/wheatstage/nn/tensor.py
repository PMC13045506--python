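"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: every operation returns a new :class:`Tensor`
holding the forward value and a closure that propagates the adjoint to its
parents.  ``backward()`` on a scalar runs the tape in reverse topological
order.  Only the operations the network needs are implemented; convolution
and max-pooling are primitives (im2col / col2im) so the heavy lifting stays
inside BLAS.

All arrays are float32 unless a caller says otherwise.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = self.data + other.data

        def backward(g):
            self._maybe(g, lambda: _unbroadcast(g, self.shape))
            other._maybe(g, lambda: _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def _maybe(self, g, fn):
        if self.requires_grad:
            self._accum(fn())

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other, dtype=np.float32))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = self.data * other.data

        def backward(g):
            self._maybe(g, lambda: _unbroadcast(g * other.data, self.shape))
            other._maybe(g, lambda: _unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = self.data / other.data

        def backward(g):
            self._maybe(g, lambda: _unbroadcast(g / other.data, self.shape))
            other._maybe(g, lambda: _unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(_as_array(other)) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._maybe(g, lambda: _unbroadcast(g * p * self.data ** (p - 1), self.shape))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            self._maybe(g, lambda: _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape))
            other._maybe(g, lambda: _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._maybe(g, lambda: g.reshape(src))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._maybe(g, lambda: g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        src_shape = self.shape

        def backward(g):
            def grad():
                dx = np.zeros(src_shape, dtype=np.float32)
                np.add.at(dx, idx, g)
                return dx
            self._maybe(g, grad)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        src = self.shape

        def backward(g):
            def grad():
                gg = g
                if not keepdims and axis is not None:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    ax = tuple(a % len(src) for a in ax)
                    gg = np.expand_dims(gg, ax)
                return np.broadcast_to(gg, src).astype(np.float32)
            self._maybe(g, grad)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            def grad():
                expanded = np.expand_dims(out_data, axis) if not keepdims else out_data
                mask = (self.data == expanded).astype(np.float32)
                mask /= np.maximum(mask.sum(axis=axis, keepdims=True), 1.0)
                gg = np.expand_dims(g, axis) if not keepdims else g
                return mask * gg
            self._maybe(g, grad)

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            self._maybe(g, lambda: g * (self.data > 0))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._maybe(g, lambda: g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data.astype(np.float64)
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = (x * phi).astype(np.float32)

        def backward(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            self._maybe(g, lambda: g * (phi + x * pdf).astype(np.float32))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._maybe(g, lambda: g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._maybe(g, lambda: g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- backward driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar output")
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node is not self:
                    node.grad = None  # free intermediate adjoints


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``targets`` under ``logits``."""
    n = logits.shape[0]
    logp = log_softmax(logits, axis=1)
    picked = logp[np.arange(n), np.asarray(targets, dtype=np.intp)]
    return -picked.mean()


# -- convolution primitives ----------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (n, c, oh, ow, kh, kw) -> (n*oh*ow, c*kh*kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int,
            oh: int, ow: int) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    d6 = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d6[:, :, :, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); weight is [Cout, Cin, kh, kw]."""
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {cin}")
    n = x.shape[0]
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out_data = out.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)
    xshape = x.shape

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, cout)
        if weight.requires_grad:
            weight._accum((gmat.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = gmat @ wmat
            x._accum(_col2im(dcols, xshape, kh, kw, stride, pad, oh, ow))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    n, c, h, w = x.shape
    neg = np.float32(-np.inf)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=neg)
    oh = (h + 2 * pad - kernel) // stride + 1
    ow = (w + 2 * pad - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(n, c, oh, ow, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        def grad():
            dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
            ni, ci, oi, oj = np.indices((n, c, oh, ow), sparse=False)
            ri = oi * stride + idx // kernel
            cj = oj * stride + idx % kernel
            np.add.at(dxp, (ni, ci, ri, cj), g)
            if pad:
                return dxp[:, :, pad:-pad, pad:-pad]
            return dxp
        x._maybe(g, grad)

    return Tensor._make(out_data, (x,), backward)


def avg_pool2d_to(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Adaptive average pooling for integer reduction factors."""
    n, c, h, w = x.shape
    th, tw = out_hw
    if h % th or w % tw:
        raise ValueError(f"avg_pool2d_to: {h}x{w} not divisible by target {th}x{tw}")
    fh, fw = h // th, w // tw
    return x.reshape(n, c, th, fh, tw, fw).mean(axis=(3, 5))
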