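"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray plus an optional gradient; ops
build a graph of backward closures which :meth:`Tensor.backward` replays in
reverse topological order.  The op set is exactly what the segmentation
networks in this package need: broadcasting arithmetic, elementwise
nonlinearities, reductions, matmul, 2-D convolution (grouped/depthwise
included), batch norm, max pooling, nearest upsampling, concatenation and
slicing, softmax/log-softmax, and a fused binary cross-entropy with logits.

Convolution uses im2col + BLAS matmul forward and k² strided slice-adds for
the input gradient, which keeps desk-scale CPU training practical.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "no_grad", "as_tensor"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- operator sugar ------------------------------------------------------

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

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*parents: Tensor) -> bool:
    return _grad_enabled and any(
        isinstance(p, Tensor) and (p.requires_grad or p._parents or p._backward)
        for p in parents
    )


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _track(*parents) and backward is not None:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return _make(out, (a, b), lambda g: [(a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape))])


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data
    return _make(out, (a, b), lambda g: [(a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(-g, b.data.shape))])


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return _make(
        out,
        (a, b),
        lambda g: [
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        ],
    )


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data
    return _make(
        out,
        (a, b),
        lambda g: [
            (a, _unbroadcast(g / b.data, a.data.shape)),
            (b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)),
        ],
    )


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = a.data**p
    return _make(out, (a,), lambda g: [(a, g * p * a.data ** (p - 1))])


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return _make(out, (a,), lambda g: [(a, g * out)])


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), lambda g: [(a, g / a.data)])


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return _make(out, (a,), lambda g: [(a, g * 0.5 / np.maximum(out, 1e-12))])


def arctan(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.arctan(a.data), (a,), lambda g: [(a, g / (1.0 + a.data * a.data))])


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.maximum(a.data, b.data)
    mask = (a.data >= b.data).astype(np.float32)
    return _make(
        out,
        (a, b),
        lambda g: [
            (a, _unbroadcast(g * mask, a.data.shape)),
            (b, _unbroadcast(g * (1.0 - mask), b.data.shape)),
        ],
    )


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.minimum(a.data, b.data)
    mask = (a.data <= b.data).astype(np.float32)
    return _make(
        out,
        (a, b),
        lambda g: [
            (a, _unbroadcast(g * mask, a.data.shape)),
            (b, _unbroadcast(g * (1.0 - mask), b.data.shape)),
        ],
    )


def clamp(a, lo=None, hi=None) -> Tensor:
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    inside = np.ones_like(a.data)
    if lo is not None:
        inside *= a.data >= lo
    if hi is not None:
        inside *= a.data <= hi
    return _make(out, (a,), lambda g: [(a, g * inside)])


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = (a.data > 0).astype(np.float32)
    return _make(a.data * mask, (a,), lambda g: [(a, g * mask)])


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = _sigmoid_np(a.data)
    return _make(out, (a,), lambda g: [(a, g * out * (1.0 - out))])


def sigmoid_np(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function on a plain ndarray."""
    return _sigmoid_np(np.asarray(x))


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def silu(a) -> Tensor:
    a = as_tensor(a)
    s = _sigmoid_np(a.data)
    out = a.data * s
    return _make(out, (a,), lambda g: [(a, g * (s + a.data * s * (1.0 - s)))])


# ---------------------------------------------------------------------------
# reductions / shaping


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        return [(a, np.broadcast_to(gg, a.data.shape).astype(np.float32))]

    return _make(out, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod([a.data.shape[i] for i in np.atleast_1d(axis)])
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = a.data.reshape(shape)
    return _make(out, (a,), lambda g: [(a, g.reshape(a.data.shape))])


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)
    return _make(a.data.transpose(axes), (a,), lambda g: [(a, g.transpose(inv))])


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return _make(out, tuple(tensors), backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    a = as_tensor(a)
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out = a.data[sl]

    def backward(g):
        full = np.zeros_like(a.data)
        full[sl] = g
        return [(a, full)]

    return _make(out, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return [(a, _unbroadcast(ga, a.data.shape)), (b, _unbroadcast(gb, b.data.shape))]

    return _make(out, (a, b), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return [(a, s * (g - dot))]

    return _make(s, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    s = np.exp(out)

    def backward(g):
        return [(a, g - s * g.sum(axis=axis, keepdims=True))]

    return _make(out, (a,), backward)


def bce_with_logits(logits, targets) -> Tensor:
    """Elementwise stable binary cross-entropy; ``targets`` is a constant."""
    a = as_tensor(logits)
    t = np.asarray(targets.data if isinstance(targets, Tensor) else targets, dtype=np.float32)
    x = a.data
    out = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    return _make(out, (a,), lambda g: [(a, g * (_sigmoid_np(x) - t))])


# ---------------------------------------------------------------------------
# spatial ops


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) over (B, C, H, W) tensors.

    ``groups == 1`` is the dense path; ``groups == in_channels`` the
    depthwise path (with channel multiplier); other group counts fall back
    to per-group dense convolutions.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.data.shape
    Cout, Cpg, kh, kw = w.data.shape
    s, p = stride, padding
    OH = (H + 2 * p - kh) // s + 1
    OW = (W + 2 * p - kw) // s + 1
    xp = _pad_hw(x.data, p)

    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]  # B,C,OH,OW,kh,kw

    if groups == 1:
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * OH * OW, C * kh * kw)
        wmat = w.data.reshape(Cout, -1)
        out = (cols @ wmat.T).reshape(B, OH, OW, Cout).transpose(0, 3, 1, 2)
    elif groups == C and Cpg == 1:
        m = Cout // C
        wr = w.data.reshape(C, m, kh, kw)
        out = np.einsum("bchwuv,cmuv->bcmhw", win, wr, optimize=True).reshape(B, Cout, OH, OW)
        cols = None
    else:
        # generic grouped path: loop over groups through the dense machinery
        cg_in, cg_out = C // groups, Cout // groups
        parts = []
        for g_ in range(groups):
            xs = narrow(x, 1, g_ * cg_in, cg_in)
            ws = narrow(w, 0, g_ * cg_out, cg_out)
            parts.append(conv2d(xs, ws, None, stride, padding, 1))
        out_t = concat(parts, axis=1)
        if b is not None:
            out_t = add(out_t, reshape(as_tensor(b), (1, Cout, 1, 1)))
        return out_t

    if b is not None:
        bt = as_tensor(b)
        out = out + bt.data.reshape(1, Cout, 1, 1)
    else:
        bt = None

    def backward(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        grads = []
        if groups == 1:
            gmat = g.transpose(0, 2, 3, 1).reshape(B * OH * OW, Cout)
            dw = (gmat.T @ cols).reshape(w.data.shape)
            dcols = (gmat @ w.data.reshape(Cout, -1)).reshape(B, OH, OW, C, kh, kw)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u : u + s * OH : s, v : v + s * OW : s] += dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
        else:  # depthwise
            m = Cout // C
            gr = g.reshape(B, C, m, OH, OW)
            wr = w.data.reshape(C, m, kh, kw)
            dw = np.einsum("bchwuv,bcmhw->cmuv", win, gr, optimize=True).reshape(w.data.shape)
            dwin = np.einsum("cmuv,bcmhw->bchwuv", wr, gr, optimize=True)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u : u + s * OH : s, v : v + s * OW : s] += dwin[:, :, :, :, u, v]
        dx = dxp[:, :, p : p + H, p : p + W] if p else dxp
        grads.append((x, dx))
        grads.append((w, dw))
        if bt is not None:
            grads.append((bt, g.sum(axis=(0, 2, 3)).reshape(bt.data.shape)))
        return grads

    parents = (x, w) if bt is None else (x, w, bt)
    return _make(out, parents, backward)


def max_pool2d(x, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x.data
    OH = (H + 2 * p - k) // s + 1
    OW = (W + 2 * p - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    flat = win.reshape(B, C, OH, OW, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        du, dv = np.divmod(arg, k)
        bi, ci, oi, oj = np.indices((B, C, OH, OW))
        rows = oi * s + du
        cols = oj * s + dv
        np.add.at(dxp, (bi, ci, rows, cols), g)
        return [(x, dxp[:, :, p : p + H, p : p + W] if p else dxp)]

    return _make(out.astype(np.float32), (x,), backward)


def upsample_nearest2x(x) -> Tensor:
    x = as_tensor(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        B, C, H2, W2 = g.shape
        return [(x, g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))]

    return _make(out, (x,), backward)


def batch_norm(
    x,
    gamma,
    beta,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.03,
    eps: float = 1e-3,
) -> Tensor:
    """Channel-wise batch normalisation over (B, C, H, W)."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    xd = x.data
    if training:
        axes = (0, 2, 3)
        mu = xd.mean(axis=axes)
        var = xd.var(axis=axes)
        n = xd.shape[0] * xd.shape[2] * xd.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * n / max(n - 1, 1)
    else:
        mu, var = running_mean, running_var
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * ivstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        axes = (0, 2, 3)
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        dxhat = g * gamma.data[None, :, None, None]
        if training:
            n = xd.shape[0] * xd.shape[2] * xd.shape[3]
            dx = (
                ivstd[None, :, None, None]
                / n
                * (
                    n * dxhat
                    - dxhat.sum(axis=axes, keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
                )
            )
        else:
            dx = dxhat * ivstd[None, :, None, None]
        return [(x, dx.astype(np.float32)), (gamma, dgamma), (beta, dbeta)]

    return _make(out.astype(np.float32), (x, gamma, beta), backward)
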