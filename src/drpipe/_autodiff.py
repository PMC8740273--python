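"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the desk-scale classifiers in
:mod:`drpipe.models`: dense and 3x3/7x7 convolutions (stride 1), 2x2 max
pooling, ReLU/sigmoid, axis reductions, concatenation, broadcasting
arithmetic, and a fused softmax cross-entropy with per-sample weights.
float64 throughout — exactness of the freeze contract matters more than
speed at this scale.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "mean",
    "amax",
    "concat",
    "conv2d",
    "maxpool2",
    "softmax",
    "softmax_cross_entropy",
    "backward",
]


class Tensor:
    """A numpy array plus the graph edges needed for backprop."""

    __slots__ = ("data", "grad", "parents", "bw")

    def __init__(self, data, parents=(), bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = parents
        self.bw = bw  # callable(grad) -> tuple of parent grads

    @property
    def shape(self):
        return self.data.shape

    # -- operators ---------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))
        out.bw = lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))
        out.bw = lambda g: (
            _unbroadcast(g * other.data, self.data.shape),
            _unbroadcast(g * self.data, other.data.shape),
        )
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))
        out.bw = lambda g: (g @ other.data.T, self.data.T @ g)
        return out

    def reshape(self, *shape):
        src = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))
        out.bw = lambda g: (g.reshape(src),)
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum *grad* down to *shape* (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))
    out.bw = lambda g: (g * (x.data > 0),)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, (x,))
    out.bw = lambda g: (g * s * (1.0 - s),)
    return out


def mean(x: Tensor, axes: tuple[int, ...], keepdims: bool = False) -> Tensor:
    out = Tensor(x.data.mean(axis=axes, keepdims=keepdims), (x,))
    count = np.prod([x.data.shape[a] for a in axes])

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return (np.broadcast_to(g, x.data.shape) / count,)

    out.bw = bw
    return out


def amax(x: Tensor, axes: tuple[int, ...], keepdims: bool = False) -> Tensor:
    """Max over *axes*; gradient splits evenly across tied maxima."""
    kept = x.data.max(axis=axes, keepdims=True)
    out = Tensor(kept if keepdims else np.squeeze(kept, axis=axes), (x,))

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        mask = (x.data == kept).astype(np.float64)
        mask /= mask.sum(axis=axes, keepdims=True)
        return (np.broadcast_to(g, x.data.shape) * mask,)

    out.bw = bw
    return out


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out.bw = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, stride 1.

    x: (N, C, H, W); w: (F, C, kh, kw); b: (F,).
    """
    kh, kw = w.data.shape[2:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out_data = np.einsum("nchwij,fcij->nfhw", win, w.data, optimize=True)
    out_data += b.data[None, :, None, None]
    out = Tensor(out_data, (x, w, b))
    ho, wo = out_data.shape[2:]

    def bw(g):
        dw = np.einsum("nchwij,nfhw->fcij", win, g, optimize=True)
        db = g.sum(axis=(0, 2, 3))
        dwin = np.einsum("nfhw,fcij->nchwij", g, w.data, optimize=True)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + ho, j : j + wo] += dwin[:, :, :, :, i, j]
        if pad:
            dx = dxp[:, :, pad:-pad, pad:-pad]
        else:
            dx = dxp
        return dx, dw, db

    out.bw = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""
    n, c, h, w = x.data.shape
    ho, wo = h // 2, w // 2
    xc = x.data[:, :, : ho * 2, : wo * 2]
    windows = xc.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = windows.argmax(axis=-1)
    out = Tensor(np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0], (x,))

    def bw(g):
        dwin = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = np.zeros_like(x.data)
        dx[:, :, : ho * 2, : wo * 2] = (
            dwin.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * 2, wo * 2)
        )
        return (dx,)

    out.bw = bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a plain array (forward-only helper)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray, sample_weights: np.ndarray | None = None) -> Tensor:
    """Mean of per-sample weighted cross-entropy; numerically stable.

    Per-sample loss is ``w_i * CE_i``, so a sample's loss contribution
    scales exactly with its class weight.
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    w = np.ones(n) if sample_weights is None else np.asarray(sample_weights, dtype=np.float64)
    p = softmax(logits.data)
    ce = -np.log(np.clip(p[np.arange(n), y], 1e-300, None))
    out = Tensor((w * ce).mean(), (logits,))

    def bw(g):
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (g * w / n)[:, None]
        return (dlogits,)

    out.bw = bw
    return out


def backward(loss: Tensor) -> None:
    """Reverse-topological backprop from a scalar loss."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    for t in topo:
        t.grad = None
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node.bw is None or node.grad is None:
            continue
        for parent, g in zip(node.parents, node.bw(node.grad)):
            if parent.grad is None:
                parent.grad = g.copy()
            else:
                parent.grad = parent.grad + g


class Adam:
    """Adaptive-moment optimizer over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
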