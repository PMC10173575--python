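"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the segmentation networks in this
package: broadcast arithmetic, reductions, elementwise nonlinearities,
stride-1 2D convolution, 2x2 max pooling, bilinear resampling and channel
concatenation.  Everything is float64 for deterministic, testable numerics.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

DTYPE = np.float64


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """An array node in the computation tape.

    ``parents`` is a sequence of ``(tensor, vjp)`` pairs where ``vjp`` maps
    the output gradient to the contribution for that parent.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff -----------------------------------------------------------
    def backward(self, seed: np.ndarray | None = None) -> None:
        """Accumulate gradients into ``.grad`` of every reachable tensor."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar")
            seed = np.ones_like(self.data)
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
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(seed, dtype=DTYPE)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in node._parents:
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(a: Tensor, b: Tensor | None = None) -> bool:
    live = a.requires_grad or a._parents
    if b is not None:
        live = live or b.requires_grad or b._parents
    return bool(live)


def _node(data, parents) -> Tensor:
    keep = [(p, f) for p, f in parents if p.requires_grad or p._parents]
    return Tensor(data, parents=keep)


# -- arithmetic --------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data + b.data
    return _node(out, [(a, lambda g: _unbroadcast(g, a.data.shape)),
                       (b, lambda g: _unbroadcast(g, b.data.shape))])


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data * b.data
    return _node(out, [(a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
                       (b, lambda g: _unbroadcast(g * a.data, b.data.shape))])


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data / b.data
    return _node(out, [
        (a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
        (b, lambda g: _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)),
    ])


def power(a, exponent: float) -> Tensor:
    a = astensor(a)
    out = a.data ** exponent
    return _node(out, [(a, lambda g: g * exponent * a.data ** (exponent - 1))])


def sqrt(a) -> Tensor:
    a = astensor(a)
    out = np.sqrt(a.data)
    return _node(out, [(a, lambda g: g * 0.5 / np.sqrt(a.data))])


def exp(a) -> Tensor:
    a = astensor(a)
    out = np.exp(a.data)
    return _node(out, [(a, lambda g: g * out)])


def log(a) -> Tensor:
    a = astensor(a)
    out = np.log(a.data)
    return _node(out, [(a, lambda g: g / a.data)])


# -- reductions / shape ------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        gg = g
        if not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            for ax_i in sorted(a_i % a.data.ndim for a_i in ax):
                gg = np.expand_dims(gg, ax_i)
        return np.broadcast_to(gg, a.data.shape).copy()

    return _node(out, [(a, vjp)])


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out = a.data.reshape(shape)
    return _node(out, [(a, lambda g: g.reshape(a.data.shape))])


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Differentiable slice of `length` entries along `axis` starting at `start`."""
    a = astensor(a)
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out = a.data[sl]

    def vjp(g):
        ga = np.zeros_like(a.data)
        ga[sl] = g
        return ga

    return _node(out, [(a, vjp)])


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return _node(out, [(t, make_vjp(i)) for i, t in enumerate(tensors)])


# -- nonlinearities ----------------------------------------------------------

def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    return _node(a.data * mask, [(a, lambda g: g * mask)])


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out = expit(a.data)  # overflow-free for large |x|
    return _node(out, [(a, lambda g: g * out * (1.0 - out))])


def log_softmax(a, axis: int = 1) -> Tensor:
    a = astensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    ls = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))
    softmax = np.exp(ls)

    def vjp(g):
        return g - softmax * g.sum(axis=axis, keepdims=True)

    return _node(ls, [(a, vjp)])


def softmax(a, axis: int = 1) -> Tensor:
    return exp(log_softmax(a, axis=axis))


# -- spatial operations ------------------------------------------------------

def conv2d(x, w, b=None, padding: int = 0) -> Tensor:
    """Stride-1 cross-correlation of NCHW input with FCkk weights.

    Implemented as a shift-and-accumulate over the kernel footprint so no
    k^2-times-larger im2col buffer is ever materialized.
    """
    x, w = astensor(x), astensor(w)
    N, C, H, W = x.data.shape
    F, C2, kh, kw = w.data.shape
    if C != C2:
        raise ValueError(f"conv2d channel mismatch: input has {C}, weight expects {C2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    # (N,C,H,W) x (F,C) channel contraction per kernel offset
    xr = xp.reshape(N, C, -1) if (kh, kw) == (1, 1) else None
    if xr is not None:
        out = np.matmul(w.data.reshape(F, C), xr).reshape(N, F, Ho, Wo)
    else:
        out = np.zeros((N, F, Ho, Wo), dtype=DTYPE)
        for i in range(kh):
            for j in range(kw):
                seg = xp[:, :, i:i + Ho, j:j + Wo].reshape(N, C, Ho * Wo)
                out += np.matmul(w.data[:, :, i, j], seg).reshape(N, F, Ho, Wo)
    if b is not None:
        b = astensor(b)
        out = out + b.data.reshape(1, F, 1, 1)

    def vjp_x(g):
        gxp = np.zeros_like(xp)
        gflat = g.reshape(N, F, Ho * Wo)
        for i in range(kh):
            for j in range(kw):
                contrib = np.matmul(w.data[:, :, i, j].T, gflat)
                gxp[:, :, i:i + Ho, j:j + Wo] += contrib.reshape(N, C, Ho, Wo)
        if padding:
            return gxp[:, :, padding:-padding, padding:-padding]
        return gxp

    def vjp_w(g):
        gw = np.empty((F, C, kh, kw), dtype=DTYPE)
        gflat = g.reshape(N, F, Ho * Wo)
        for i in range(kh):
            for j in range(kw):
                seg = xp[:, :, i:i + Ho, j:j + Wo].reshape(N, C, Ho * Wo)
                gw[:, :, i, j] = np.einsum("nfp,ncp->fc", gflat, seg, optimize=True)
        return gw

    parents = [(x, vjp_x), (w, vjp_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return _node(out, parents)


def maxpool2x(x) -> Tensor:
    """2x2 max pooling with stride 2; spatial extents must be even."""
    x = astensor(x)
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x requires even extents, got {(H, W)}")
    Ho, Wo = H // 2, W // 2
    xw = x.data.reshape(N, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, 4)
    idx = xw.argmax(axis=-1)
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        gw = np.zeros((N, C, Ho, Wo, 4), dtype=DTYPE)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        return gw.reshape(N, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)

    return _node(out, [(x, vjp)])


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix (align_corners=False convention)."""
    key = (n_out, n_in)
    m = _INTERP_CACHE.get(key)
    if m is None:
        m = np.zeros((n_out, n_in), dtype=DTYPE)
        scale = n_in / n_out
        for i in range(n_out):
            src = (i + 0.5) * scale - 0.5
            src = min(max(src, 0.0), n_in - 1.0)
            i0 = int(np.floor(src))
            i1 = min(i0 + 1, n_in - 1)
            frac = src - i0
            m[i, i0] += 1.0 - frac
            m[i, i1] += frac
        _INTERP_CACHE[key] = m
    return m


def resize_bilinear(x, target_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of NCHW tensors; differentiable, exact adjoint."""
    x = astensor(x)
    N, C, H, W = x.data.shape
    Ho, Wo = target_hw
    Mh = _interp_matrix(Ho, H)
    Mw = _interp_matrix(Wo, W)
    out = np.matmul(np.matmul(Mh, x.data), Mw.T)

    def vjp(g):
        return np.matmul(np.matmul(Mh.T, g), Mw)

    return _node(out, [(x, vjp)])


def upsample2x(x) -> Tensor:
    _, _, H, W = astensor(x).data.shape
    return resize_bilinear(x, (2 * H, 2 * W))
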