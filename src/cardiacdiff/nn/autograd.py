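"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the primitives the denoising networks in this
package need: broadcasted arithmetic, matmul (optionally batched), reductions,
shape ops, a handful of nonlinearities and a fused 2-D convolution.  Gradients
are accumulated into ``Tensor.grad`` by :func:`backward`, which walks the tape
in reverse topological order.  A module-level ``no_grad`` context disables tape
recording for inference paths (sampling, evaluation).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype != np.float32 and arr.dtype != np.float64:
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def backward(self, grad: Optional[np.ndarray] = None):
        backward(self, grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data, parents: Sequence[Tensor], bwd: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = bwd
    return out


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True) if g.dtype != t.data.dtype else g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    nd_extra = g.ndim - len(shape)
    if nd_extra > 0:
        g = g.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- arithmetic --------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), bwd)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(-g, b.shape))

    return _make(out_data, (a, b), bwd)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), bwd)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def bwd(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _make(out_data, (a, b), bwd)


def power(a, p: float):
    a = as_tensor(a)
    out_data = a.data ** p

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * p * a.data ** (p - 1))

    return _make(out_data, (a,), bwd)


def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * out_data)

    return _make(out_data, (a,), bwd)


def sqrt(a):
    a = as_tensor(a)
    out_data = np.sqrt(a.data)

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * 0.5 / out_data)

    return _make(out_data, (a,), bwd)


def sigmoid(a):
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bwd)


def silu(a):
    """x * sigmoid(x), the activation used throughout the backbones."""
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), bwd)


def tanh(a):
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def bwd(g):
        if a.requires_grad:
            _accum(a, g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), bwd)


def log(a):
    a = as_tensor(a)
    out_data = np.log(a.data)

    def bwd(g):
        if a.requires_grad:
            _accum(a, g / a.data)

    return _make(out_data, (a,), bwd)


# -- reductions / shape ------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is None:
            _accum(a, np.broadcast_to(g, a.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g, a.shape))

    return _make(out_data, (a,), bwd)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    denom = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )

    def bwd(g):
        if not a.requires_grad:
            return
        g = np.asarray(g) / denom
        if axis is None:
            _accum(a, np.broadcast_to(g, a.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g, a.shape))

    return _make(out_data, (a,), bwd)


def reshape(a, shape):
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def bwd(g):
        if a.requires_grad:
            _accum(a, g.reshape(a.shape))

    return _make(out_data, (a,), bwd)


def transpose(a, axes):
    a = as_tensor(a)
    axes = tuple(axes)
    out_data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def bwd(g):
        if a.requires_grad:
            _accum(a, g.transpose(inv))

    return _make(out_data, (a,), bwd)


def getitem(a, idx):
    a = as_tensor(a)
    out_data = a.data[idx]

    def bwd(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            _accum(a, full)

    return _make(out_data, (a,), bwd)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _accum(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), bwd)


def pad2d(a, p: int):
    """Zero-pad the two trailing spatial axes of a (B, C, H, W) tensor."""
    a = as_tensor(a)
    out_data = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p)))

    def bwd(g):
        if a.requires_grad:
            _accum(a, g[:, :, p:-p, p:-p])

    return _make(out_data, (a,), bwd)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            _accum(a, _unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            _accum(b, _unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), bwd)


def softmax(a, axis=-1):
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            _accum(a, out_data * (g - dot))

    return _make(out_data, (a,), bwd)


# -- convolution -------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """2-D cross-correlation: x (B,Cin,H,W), w (Cout,Cin,k,k), b (Cout,)."""
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    xd = x.data
    B, Cin, H, W = xd.shape
    Cout, Cin2, k, _ = w.shape
    if Cin != Cin2:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, weight {Cin2}")
    if k == 1 and stride == 1 and padding == 0:
        return _conv1x1(x, w, b, B, Cin, Cout, H, W)
    if stride == 1:
        return _conv_shifted(x, w, b, padding)
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = xd
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # B,Cin,Ho,Wo,k,k
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, Ho * Wo, Cin * k * k)
    wmat = w.data.reshape(Cout, Cin * k * k).T  # (Cin*k*k, Cout)
    out = cols @ wmat  # B, Ho*Wo, Cout
    if b is not None:
        out = out + b.data
    out_data = np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(B, Cout, Ho, Wo)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B, Ho * Wo, Cout)
        if w.requires_grad:
            dw = np.tensordot(gmat, cols, axes=([0, 1], [0, 1]))  # (Cout, Cin*k*k)
            _accum(w, dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            _accum(b, gmat.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = gmat @ wmat.T  # B, Ho*Wo, Cin*k*k
            dcols = dcols.reshape(B, Ho, Wo, Cin, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros((B, Cin, Hp, Wp), dtype=xd.dtype)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += dcols[:, :, :, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            _accum(x, dxp)

    return _make(out_data, tuple(t for t in (x, w, b) if t is not None), bwd)


def _conv_shifted(x, w, b, padding: int):
    """Stride-1 convolution as k² shifted tensordots (avoids im2col copies)."""
    xd = x.data
    B, Cin, H, W = xd.shape
    Cout, _, k, _ = w.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else xd
    Ho = xp.shape[2] - k + 1
    Wo = xp.shape[3] - k + 1
    acc = np.zeros((B, Ho, Wo, Cout), dtype=xd.dtype)
    for i in range(k):
        for j in range(k):
            acc += np.tensordot(xp[:, :, i:i + Ho, j:j + Wo], w.data[:, :, i, j],
                                axes=([1], [1]))
    if b is not None:
        acc += b.data
    out_data = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))

    def bwd(g):
        gperm = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (B,Ho,Wo,Cout)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(k):
                for j in range(k):
                    dw[:, :, i, j] = np.tensordot(
                        gperm, xp[:, :, i:i + Ho, j:j + Wo], axes=([0, 1, 2], [0, 2, 3]))
            _accum(w, dw)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + Ho, j:j + Wo] += np.tensordot(
                        gperm, w.data[:, :, i, j], axes=([3], [0])).transpose(0, 3, 1, 2)
            _accum(x, dxp[:, :, padding:-padding, padding:-padding] if padding else dxp)

    return _make(out_data, tuple(t for t in (x, w, b) if t is not None), bwd)


def _conv1x1(x, w, b, B, Cin, Cout, H, W):
    """Pointwise convolution as a single matrix product (no im2col)."""
    xm = x.data.reshape(B, Cin, H * W)
    wm = w.data.reshape(Cout, Cin)
    out = np.matmul(wm[None], xm)  # (B, Cout, HW)
    if b is not None:
        out = out + b.data[None, :, None]
    out_data = out.reshape(B, Cout, H, W)

    def bwd(g):
        gm = g.reshape(B, Cout, H * W)
        if w.requires_grad:
            dw = np.tensordot(gm, xm, axes=([0, 2], [0, 2]))  # (Cout, Cin)
            _accum(w, dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            _accum(b, gm.sum(axis=(0, 2)))
        if x.requires_grad:
            dx = np.matmul(wm.T[None], gm).reshape(B, Cin, H, W)
            _accum(x, dx)

    return _make(out_data, tuple(t for t in (x, w, b) if t is not None), bwd)


def upsample_nearest2x(a):
    a = as_tensor(a)
    out_data = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(g):
        if a.requires_grad:
            B, C, H2, W2 = g.shape
            _accum(a, g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    return _make(out_data, (a,), bwd)


# -- backward driver ---------------------------------------------------------

def backward(out: Tensor, grad: Optional[np.ndarray] = None):
    """Backpropagate from ``out`` through the recorded tape."""
    if not out.requires_grad:
        raise RuntimeError("output does not require grad")
    if grad is None:
        if out.size != 1:
            raise RuntimeError("grad must be supplied for non-scalar outputs")
        grad = np.ones_like(out.data)
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(out, False)]
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
    _accum(out, np.asarray(grad, dtype=out.data.dtype))
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
            # free intermediate grads/graph to bound memory
            if node is not out:
                node._backward = None
                node._parents = ()
                node.grad = None
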