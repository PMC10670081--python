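"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the spectral network needs: broadcasting
arithmetic, matmul, ReLU/sigmoid, axis reductions, reshape, fused 1-D
convolution / max-pooling / batch-norm, a cross-entropy head, and an Adam
optimizer.  Forward-only callers can pass plain ``numpy`` arrays to the
dispatch helpers (:func:`relu`, :func:`amean`, ...) and never touch
:class:`Tensor`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "relu",
    "sigmoid",
    "amean",
    "amax",
    "asum",
    "conv1d",
    "max_pool1d",
    "batch_norm1d",
    "dropout",
    "cross_entropy",
    "Adam",
]

_GRAD_ENABLED = True

# float64 by default (exact oracles, finite-difference checks); training
# switches to float32 for speed via use_dtype().
DTYPE = np.float64


class use_dtype:
    """Context manager selecting the dtype newly created Tensors use."""

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        global DTYPE
        self._prev = DTYPE
        DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global DTYPE
        DTYPE = self._prev
        return False


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[["Tensor"], Callable[[], None]] | None):
        needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs)
        if needs and backward is not None:
            out._prev = tuple(parents)
            out._backward = backward(out)
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- conveniences ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=DTYPE))

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out):
            def run():
                if a.requires_grad:
                    a._accum(_unbroadcast(out.grad, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(out.grad, b.data.shape))
            return run

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out):
            def run():
                if a.requires_grad:
                    a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(out.grad * a.data, b.data.shape))
            return run

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __truediv__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out):
            def run():
                if a.requires_grad:
                    a._accum(_unbroadcast(out.grad / b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(-out.grad * a.data / (b.data ** 2), b.data.shape))
            return run

        return Tensor._result(a.data / b.data, (a, b), bw)

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bw(out):
            def run():
                if a.requires_grad:
                    a._accum(out.grad * e * a.data ** (e - 1.0))
            return run

        return Tensor._result(a.data ** e, (a,), bw)

    def __matmul__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out):
            def run():
                if a.requires_grad:
                    ga = out.grad @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ out.grad
                    b._accum(_unbroadcast(gb, b.data.shape))
            return run

        return Tensor._result(a.data @ b.data, (a, b), bw)

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def bw(out):
            def run():
                if a.requires_grad:
                    a._accum(out.grad * mask)
            return run

        return Tensor._result(np.where(mask, a.data, 0.0), (a,), bw)

    def sigmoid(self):
        a = self
        s = _stable_sigmoid(a.data)

        def bw(out):
            def run():
                if a.requires_grad:
                    a._accum(out.grad * s * (1.0 - s))
            return run

        return Tensor._result(s, (a,), bw)

    def exp(self):
        a = self
        e = np.exp(a.data)

        def bw(out):
            def run():
                if a.requires_grad:
                    a._accum(out.grad * e)
            return run

        return Tensor._result(e, (a,), bw)

    def log(self):
        a = self

        def bw(out):
            def run():
                if a.requires_grad:
                    a._accum(out.grad / a.data)
            return run

        return Tensor._result(np.log(a.data), (a,), bw)

    # -- reductions and shaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(out):
            def run():
                if not a.requires_grad:
                    return
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            return run

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[ax] for ax in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def bw(out):
            def run():
                if not a.requires_grad:
                    return
                g = out.grad
                if not keepdims:
                    g = np.expand_dims(g, axis)
                gin = np.zeros_like(a.data)
                np.put_along_axis(gin, np.expand_dims(idx, axis), g, axis=axis)
                a._accum(gin)
            return run

        return Tensor._result(out_data, (a,), bw)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(out):
            def run():
                if a.requires_grad:
                    a._accum(out.grad.reshape(orig))
            return run

        return Tensor._result(a.data.reshape(shape), (a,), bw)


# ---------------------------------------------------------------------------
# dispatch helpers: work on Tensor or plain ndarray
# ---------------------------------------------------------------------------

def relu(x):
    if isinstance(x, Tensor):
        return x.relu()
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def sigmoid(x):
    if isinstance(x, Tensor):
        return x.sigmoid()
    return _stable_sigmoid(np.asarray(x, dtype=float))


def amean(x, axis):
    if isinstance(x, Tensor):
        return x.mean(axis=axis)
    return np.asarray(x, dtype=float).mean(axis=axis)


def amax(x, axis):
    if isinstance(x, Tensor):
        return x.max(axis=axis)
    return np.asarray(x, dtype=float).max(axis=axis)


def asum(x, axis):
    if isinstance(x, Tensor):
        return x.sum(axis=axis)
    return np.asarray(x, dtype=float).sum(axis=axis)


def reshape(x, shape):
    if isinstance(x, Tensor):
        return x.reshape(shape)
    return np.asarray(x).reshape(shape)


# ---------------------------------------------------------------------------
# fused network layers
# ---------------------------------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor, padding: int = 0) -> Tensor:
    """Cross-correlation along the last axis.

    ``x``: (N, C_in, L); ``w``: (C_out, C_in, K); ``b``: (C_out,).
    Symmetric zero padding of ``padding`` on each side, stride 1.
    """
    x, w, b = Tensor._coerce(x), Tensor._coerce(w), Tensor._coerce(b)
    n, c_in, length = x.data.shape
    c_out, c_in_w, k = w.data.shape
    if c_in != c_in_w:
        raise ValueError(f"conv1d channel mismatch: input has {c_in}, kernel expects {c_in_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    l_out = xp.shape[2] - k + 1
    # im2col to a GEMM-friendly layout: (N*L_out, C_in*K)
    cols = np.ascontiguousarray(
        sliding_window_view(xp, k, axis=2).transpose(0, 2, 1, 3)).reshape(
            n * l_out, c_in * k)
    w2 = w.data.reshape(c_out, c_in * k)
    out_data = (cols @ w2.T).reshape(n, l_out, c_out).transpose(0, 2, 1)
    out_data = np.ascontiguousarray(out_data) + b.data[None, :, None]

    def bw(out):
        def run():
            g = out.grad                                  # (N, C_out, L_out)
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(n * l_out, c_out)
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
            if w.requires_grad:
                w._accum((g2.T @ cols).reshape(c_out, c_in, k))
            if x.requires_grad:
                dcols = (g2 @ w2).reshape(n, l_out, c_in, k).transpose(0, 2, 1, 3)
                dxp = np.zeros_like(xp)
                for kk in range(k):
                    dxp[:, :, kk:kk + l_out] += dcols[:, :, :, kk]
                if padding:
                    dxp = dxp[:, :, padding:-padding]
                x._accum(dxp)
        return run

    return Tensor._result(out_data, (x, w, b), bw)


def max_pool1d(x: Tensor, kernel: int = 2, stride: int | None = None) -> Tensor:
    """Non-overlapping max pooling with floor on the ragged tail."""
    if stride is None:
        stride = kernel
    if stride != kernel:
        raise NotImplementedError("only non-overlapping pooling (stride == kernel) is supported")
    x = Tensor._coerce(x)
    n, c, length = x.data.shape
    l_out = length // kernel
    if l_out < 1:
        raise ValueError(f"input length {length} shorter than pooling kernel {kernel}")
    xv = x.data[:, :, :l_out * kernel].reshape(n, c, l_out, kernel)
    idx = np.argmax(xv, axis=3)
    out_data = np.take_along_axis(xv, idx[..., None], axis=3)[..., 0]

    def bw(out):
        def run():
            if not x.requires_grad:
                return
            gin = np.zeros((n, c, l_out, kernel))
            np.put_along_axis(gin, idx[..., None], out.grad[..., None], axis=3)
            full = np.zeros_like(x.data)
            full[:, :, :l_out * kernel] = gin.reshape(n, c, l_out * kernel)
            x._accum(full)
        return run

    return Tensor._result(out_data, (x,), bw)


def avg_pool1d(x: Tensor, kernel: int = 2, stride: int | None = None) -> Tensor:
    """Non-overlapping average pooling with floor on the ragged tail."""
    if stride is None:
        stride = kernel
    if stride != kernel:
        raise NotImplementedError("only non-overlapping pooling (stride == kernel) is supported")
    x = Tensor._coerce(x)
    n, c, length = x.data.shape
    l_out = length // kernel
    if l_out < 1:
        raise ValueError(f"input length {length} shorter than pooling kernel {kernel}")
    out_data = x.data[:, :, :l_out * kernel].reshape(n, c, l_out, kernel).mean(axis=3)

    def bw(out):
        def run():
            if not x.requires_grad:
                return
            full = np.zeros_like(x.data)
            full[:, :, :l_out * kernel] = np.repeat(out.grad / kernel, kernel, axis=2)
            x._accum(full)
        return run

    return Tensor._result(out_data, (x,), bw)


def batch_norm1d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization for (N, C, L) feature maps.

    In training mode batch statistics are used and the running arrays are
    updated in place; in eval mode the running statistics are used.
    """
    x, gamma, beta = Tensor._coerce(x), Tensor._coerce(gamma), Tensor._coerce(beta)
    n, c, length = x.data.shape
    if not training:
        inv = 1.0 / np.sqrt(running_var + eps)
        scale = gamma.reshape(1, c, 1) * Tensor(inv.reshape(1, c, 1))
        shift = beta.reshape(1, c, 1) - scale * Tensor(running_mean.reshape(1, c, 1))
        return x * scale + shift

    m = n * length
    mu = x.data.mean(axis=(0, 2))
    var = x.data.var(axis=(0, 2))
    running_mean *= (1.0 - momentum)
    running_mean += momentum * mu
    running_var *= (1.0 - momentum)
    running_var += momentum * var * (m / max(m - 1, 1))   # unbiased for running stats
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None]) / std[None, :, None]
    out_data = gamma.data[None, :, None] * xhat + beta.data[None, :, None]

    def bw(out):
        def run():
            g = out.grad
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2)))
            if x.requires_grad:
                dxhat = g * gamma.data[None, :, None]
                mean_dxhat = dxhat.mean(axis=(0, 2))[None, :, None]
                mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2))[None, :, None]
                dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std[None, :, None]
                x._accum(dx)
        return run

    return Tensor._result(out_data, (x, gamma, beta), bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; gradient is (softmax - onehot)/N."""
    logits = Tensor._coerce(logits)
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    expv = np.exp(shifted)
    probs = expv / expv.sum(axis=1, keepdims=True)
    nll = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))
    loss = nll.mean()

    def bw(out):
        def run():
            if not logits.requires_grad:
                return
            g = probs.copy()
            g[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * g / n)
        return run

    return Tensor._result(np.asarray(loss), (logits,), bw)


class Adam:
    """Adam optimizer over a collection of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * (p.grad ** 2)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
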