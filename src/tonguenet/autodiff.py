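"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it; :meth:`Tensor.backward` runs the reverse sweep over the taped
graph. Only the operations the segmentation network needs are provided
(dense/dilated convolution, matmul, normalisation statistics, softmax,
bilinear resizing, elementwise arithmetic and shape manipulation).

Gradients accumulate in ``Tensor.grad``. Wrap inference code in
:func:`no_grad` to skip taping.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "no_grad", "cat", "conv2d", "softmax", "gelu",
           "cross_entropy", "bilinear_resize", "upsample_nearest2x", "pad2d"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big models
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node._accum(g)
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = pg.astype(np.float32, copy=False)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            return ((a, _unbroadcast(g * b.data, a.shape)),
                    (b, _unbroadcast(g * a.data, b.shape)))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            return ((a, _unbroadcast(g / b.data, a.shape)),
                    (b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape)))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __pow__(self, p: float):
        a = self
        return Tensor._make(a.data ** p, (a,),
                            lambda g: ((a, g * p * a.data ** (p - 1)),))

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

        return Tensor._make(a.data @ b.data, (a, b), bw)

    # -- reductions & shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                return ((a, np.broadcast_to(g, a.shape).copy()),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g2, a.shape).copy()),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: ((a, g.reshape(a.shape)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: ((a, g.transpose(inv)),))

    def __getitem__(self, idx):
        a = self

        def bw(g):
            out = np.zeros(a.shape, dtype=np.float32)
            out[idx] = g
            return ((a, out),)

        return Tensor._make(a.data[idx], (a,), bw)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: ((a, g * mask),))

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * out_data),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def sqrt(self):
        return self ** 0.5


# -- free functions -----------------------------------------------------------

def cat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bw)


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error GELU: x * Phi(x)."""
    a = Tensor._lift(x)
    xd = a.data.astype(np.float64)
    phi = 0.5 * (1.0 + _sp.erf(xd / np.sqrt(2.0)))
    out = (xd * phi).astype(np.float32)
    dens = np.exp(-0.5 * xd * xd) / np.sqrt(2 * np.pi)
    dgrad = (phi + xd * dens).astype(np.float32)
    return Tensor._make(out, (a,), lambda g: ((a, g * dgrad),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    a = Tensor._lift(x)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return ((a, s * (g - dot)),)

    return Tensor._make(s, (a,), bw)


def pad2d(x: Tensor, pad: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad an NCHW tensor by (top, bottom, left, right)."""
    t, b, l, r = pad
    a = Tensor._lift(x)
    data = np.pad(a.data, ((0, 0), (0, 0), (t, b), (l, r)))
    H, W = a.shape[2], a.shape[3]

    def bw(g):
        return ((a, g[:, :, t:t + H, l:l + W]),)

    return Tensor._make(data, (a,), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input.

    Effective kernel extent is (k-1)*dilation + 1; output size follows
    floor((H + 2p - (k-1)*d - 1)/s) + 1. Implemented as a loop over the
    k*k kernel taps, each tap a strided-slice matmul, which keeps both the
    forward and the col2im backward pure NumPy slicing.
    """
    x = Tensor._lift(x)
    w = Tensor._lift(w)
    N, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    if C != Cg * groups or O % groups:
        raise ValueError("channel/group mismatch")
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    Ho = (H + 2 * padding - eh) // stride + 1
    Wo = (W + 2 * padding - ew) // stride + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError(f"non-positive conv output size {(Ho, Wo)}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) \
        if padding else x.data
    Og = O // groups
    wg = w.data.reshape(groups, Og, Cg, kh, kw)
    xpg = xp.reshape(N, groups, Cg, *xp.shape[2:])
    out = np.zeros((N, groups, Og, Ho, Wo), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            tap = xpg[:, :, :, ki * dilation: ki * dilation + stride * Ho: stride,
                      kj * dilation: kj * dilation + stride * Wo: stride]
            out += np.einsum("ngchw,goc->ngohw", tap, wg[:, :, :, ki, kj],
                             optimize=True)
    out = out.reshape(N, O, Ho, Wo)
    if b is not None:
        b = Tensor._lift(b)
        out = out + b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gg = g.reshape(N, groups, Og, Ho, Wo)
        gw = np.zeros_like(wg)
        gxp = np.zeros_like(xpg)
        for ki in range(kh):
            for kj in range(kw):
                hs = slice(ki * dilation, ki * dilation + stride * Ho, stride)
                ws = slice(kj * dilation, kj * dilation + stride * Wo, stride)
                tap = xpg[:, :, :, hs, ws]
                gw[:, :, :, ki, kj] = np.einsum("ngohw,ngchw->goc", gg, tap,
                                                optimize=True)
                gxp[:, :, :, hs, ws] += np.einsum("ngohw,goc->ngchw", gg,
                                                  wg[:, :, :, ki, kj],
                                                  optimize=True)
        gx = gxp.reshape(xp.shape)
        if padding:
            gx = gx[:, :, padding:padding + H, padding:padding + W]
        grads = [(x, gx), (w, gw.reshape(w.shape))]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return Tensor._make(out, parents, bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    a = Tensor._lift(x)
    data = a.data.repeat(2, axis=2).repeat(2, axis=3)
    N, C, H, W = a.shape

    def bw(g):
        return ((a, g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))),)

    return Tensor._make(data, (a,), bw)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    pos = (np.arange(n_out) + 0.5) * scale - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (pos - lo).astype(np.float32)
    M[np.arange(n_out), lo] += 1 - frac
    M[np.arange(n_out), hi] += frac
    return M


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Separable bilinear resize of an NCHW tensor to (Ho, Wo)."""
    a = Tensor._lift(x)
    Ho, Wo = size
    H, W = a.shape[2], a.shape[3]
    if (Ho, Wo) == (H, W):
        return a
    Mr = _interp_matrix(H, Ho)
    Mc = _interp_matrix(W, Wo)
    out = np.einsum("oh,nchw,pw->ncop", Mr, a.data, Mc, optimize=True)

    def bw(g):
        return ((a, np.einsum("oh,ncop,pw->nchw", Mr, g, Mc, optimize=True)),)

    return Tensor._make(out, (a,), bw)


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy.

    logits: (N, K, H, W); target: (N, H, W) integer class map.
    """
    a = Tensor._lift(logits)
    N, K, H, W = a.shape
    z = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    idx_n, idx_h, idx_w = np.meshgrid(np.arange(N), np.arange(H), np.arange(W),
                                      indexing="ij")
    logp = z - np.log(e.sum(axis=1, keepdims=True))
    npix = N * H * W
    loss = -logp[idx_n, target, idx_h, idx_w].sum() / npix

    def bw(g):
        grad = p.copy()
        grad[idx_n, target, idx_h, idx_w] -= 1.0
        return ((a, grad * (float(g) / npix)),)

    return Tensor._make(np.float32(loss), (a,), bw)
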