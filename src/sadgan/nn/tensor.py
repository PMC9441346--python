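"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and
the closure that back-propagates into its parents.  The op set is exactly what
the segmentation networks need: broadcasting arithmetic, matmul, 2-D
convolution (stride 1, arbitrary dilation, zero same-padding), 2x2 max/average
pooling, bilinear 2x upsampling, reductions, concatenation and the usual
pointwise nonlinearities.  ``backward()`` runs a topological sort over the
recorded graph.

Gradient correctness of every op is checked against central finite
differences in the test suite; the networks rely on nothing beyond this file
for differentiation.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "no_grad", "concat", "stack_channels", "conv2d",
           "maxpool2x2", "avgpool2x2", "upsample2x_bilinear"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph recording (inference / detached passes)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _as_array(x, dtype=None):
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------- helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph to bound memory during training
                node._backward = None
                node._prev = ()
                node.grad = None if node is not self else node.grad

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out_data = self.data + o.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.shape))

        return Tensor._make(out_data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)
        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out_data = self.data - o.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(-g, o.shape))

        return Tensor._make(out_data, (self, o), bwd)

    def __rsub__(self, other):
        return Tensor(np.asarray(other, dtype=self.dtype)) - self

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out_data = self.data * o.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.shape))

        return Tensor._make(out_data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out_data = self.data / o.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / o.data, self.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(-g * self.data / (o.data ** 2), o.shape))

        return Tensor._make(out_data, (self, o), bwd)

    def __rtruediv__(self, other):
        return Tensor(np.asarray(other, dtype=self.dtype)) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        o = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ o.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ o.data.T)
            if o.requires_grad:
                o._accumulate(self.data.T @ g)

        return Tensor._make(out_data, (self, o), bwd)

    __matmul__ = matmul

    # ---------------------------------------------------------- pointwise
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        # numerically stable split by sign
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), bwd)

    def clamp_min(self, lo: float) -> "Tensor":
        mask = self.data >= lo
        out_data = np.maximum(self.data, lo)

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # ---------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the first argmax on ties."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def bwd(g):
            if g.ndim < self.ndim:
                g = np.expand_dims(g, axis)
            buf = np.zeros_like(self.data)
            np.put_along_axis(buf, np.expand_dims(idx, axis), g, axis=axis)
            self._accumulate(buf)

        out = Tensor._make(out_data, (self,), bwd)
        if not keepdims:
            out = out.reshape(tuple(np.delete(out_data.shape, axis)))
        return out

    # ---------------------------------------------------------- shape ops
    def reshape(self, shape) -> "Tensor":
        orig = self.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(out_data, (self,), bwd)

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(out_data, (self,), bwd)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def bwd(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, key, g)
            self._accumulate(buf)

        return Tensor._make(out_data, (self,), bwd)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, requires_grad={self.requires_grad})"


# ------------------------------------------------------------------ free ops

def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, ts, bwd)


def stack_channels(a: Tensor, b: Tensor) -> Tensor:
    """Stack two (N,H,W) maps into (N,2,H,W)."""
    n, h, w = a.shape
    return concat([a.reshape((n, 1, h, w)), b.reshape((n, 1, h, w))], axis=1)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0,
           dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), stride 1.

    x: (N,C,H,W); w: (O,C,kh,kw); zero padding ``padding`` on every side;
    kernel element (i,j) reads input offset (i*dilation, j*dilation).
    Implemented as im2col + one BLAS matmul.
    """
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    eh = dilation * (kh - 1) + 1  # effective kernel extent
    ew = dilation * (kw - 1) + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    ho = xp.shape[2] - eh + 1
    wo = xp.shape[3] - ew + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d: input smaller than effective kernel")
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))[..., ::dilation, ::dilation]
    # (N,C,Ho,Wo,kh,kw) -> (N*Ho*Wo, C*kh*kw)
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, c * kh * kw)
    out = col @ wmat.T
    if b is not None:
        out += b.data
    out_data = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        if w.requires_grad:
            w._accumulate((gmat.T @ col).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            dcol = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * dilation:i * dilation + ho, j * dilation:j * dilation + wo] += \
                        dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor._make(out_data, parents, bwd)


def _pool_windows(x: np.ndarray):
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"2x2 pooling needs even spatial dims, got {h}x{w}")
    return x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    win = _pool_windows(x.data)
    idx = np.argmax(win, axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        buf = np.zeros_like(win)
        np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
        buf = buf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(buf)

    return Tensor._make(out_data, (x,), bwd)


def avgpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    win = _pool_windows(x.data)
    out_data = win.mean(axis=-1)

    def bwd(g):
        buf = np.repeat(g[..., None] * 0.25, 4, axis=-1)
        buf = buf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(buf)

    return Tensor._make(out_data, (x,), bwd)


def _up1d(x: np.ndarray, axis: int) -> np.ndarray:
    """Double one spatial axis with the separable 2x bilinear kernel.

    Output sample 2i   = 0.25*x[i-1] + 0.75*x[i]   (edge-clamped)
    Output sample 2i+1 = 0.75*x[i]   + 0.25*x[i+1]
    which is 2x bilinear interpolation with half-pixel centre alignment.
    """
    x = np.moveaxis(x, axis, -1)
    left = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    right = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    out[..., 0::2] = 0.25 * left + 0.75 * x
    out[..., 1::2] = 0.75 * x + 0.25 * right
    return np.moveaxis(out, -1, axis)


def _up1d_T(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_up1d` (exact transpose, including edge clamping)."""
    g = np.moveaxis(g, axis, -1)
    ge, go = g[..., 0::2], g[..., 1::2]
    out = 0.75 * ge + 0.75 * go
    # 0.25*left contribution: out[i-1] receives from even sample 2i
    out[..., :-1] += 0.25 * ge[..., 1:]
    out[..., 0] += 0.25 * ge[..., 0]          # clamped edge
    # 0.25*right contribution: out[i+1] receives from odd sample 2i+1
    out[..., 1:] += 0.25 * go[..., :-1]
    out[..., -1] += 0.25 * go[..., -1]        # clamped edge
    return np.moveaxis(out, -1, axis)


def upsample2x_bilinear(x: Tensor) -> Tensor:
    out_data = _up1d(_up1d(x.data, 2), 3)

    def bwd(g):
        x._accumulate(_up1d_T(_up1d_T(g, 3), 2))

    return Tensor._make(out_data, (x,), bwd)
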