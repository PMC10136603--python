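"""Minimal numpy neural-network layers with forward and backward passes.

Implements exactly the pieces the 3D depthwise-separable backbone and its
dense head need: full and depthwise 3D convolutions with "same"-style
ceil-mode padding, batch normalization, ReLU, global average pooling,
linear layers, and a softmax cross-entropy loss.  All layers cache what
their backward pass needs when ``train=True``; parameters and gradients are
exposed as flat name->array dicts so an optimizer can treat a model as a
parameter tree.

Padding follows the TensorFlow "SAME" rule: an input extent ``n`` under
stride ``s`` produces ``ceil(n/s)`` outputs, with the total padding split
small-half-before / large-half-after.  This is what makes the temporal
extent follow 200 -> 100 -> 50 -> 25 -> 13 through the stride-2 stages.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "DepthwiseConv3d",
    "BatchNorm3d",
    "ReLU",
    "GlobalAvgPool3d",
    "Linear",
    "softmax",
    "softmax_cross_entropy",
    "same_ceil_padding",
    "conv_out_len",
    "Adam",
]


def conv_out_len(n: int, stride: int) -> int:
    """Output extent of a same-padded convolution: ceil(n / stride)."""
    return -(-n // stride)


def same_ceil_padding(n: int, k: int, stride: int) -> tuple[int, int]:
    """(before, after) padding so that output extent is ceil(n/stride)."""
    out = conv_out_len(n, stride)
    total = max((out - 1) * stride + k - n, 0)
    before = total // 2
    return before, total - before


class Layer:
    """Base layer: parameter/gradient registry plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        """Arrays to persist (parameters plus any buffers)."""
        return dict(self.params)


def _window_cols(x_pad: np.ndarray, k: int, stride: tuple[int, int, int]) -> np.ndarray:
    """(N, C, Do, Ho, Wo, k, k, k) view of all convolution windows."""
    win = sliding_window_view(x_pad, (k, k, k), axis=(2, 3, 4))
    sd, sh, sw = stride
    return win[:, :, ::sd, ::sh, ::sw]


def _pad_input(x: np.ndarray, k: int, stride: tuple[int, int, int]):
    pads = [same_ceil_padding(n, k, s) for n, s in zip(x.shape[2:], stride)]
    x_pad = np.pad(x, [(0, 0), (0, 0), *pads])
    return x_pad, pads


class Conv3d(Layer):
    """Full 3D convolution (pointwise when ``k=1``), same-ceil padding."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride=(1, 1, 1),
                 bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride = tuple(stride)
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k**3
        self.params["weight"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k, k)
        ).astype(np.float32)
        if bias:
            self.params["bias"] = np.zeros(out_ch, dtype=np.float32)
        self._cache = None

    def forward(self, x, train=False):
        x_pad, pads = _pad_input(x, self.k, self.stride)
        cols = _window_cols(x_pad, self.k, self.stride)
        n, _, do, ho, wo = cols.shape[:5]
        flat = cols.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            n * do * ho * wo, self.in_ch * self.k**3
        )
        w = self.params["weight"].reshape(self.out_ch, -1)
        out = flat @ w.T
        if "bias" in self.params:
            out += self.params["bias"]
        out = out.reshape(n, do, ho, wo, self.out_ch).transpose(0, 4, 1, 2, 3)
        if train:
            self._cache = (flat, x.shape, x_pad.shape, pads, (do, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, grad_out):
        flat, x_shape, pad_shape, pads, out_dhw = self._cache
        n = x_shape[0]
        do, ho, wo = out_dhw
        go = grad_out.transpose(0, 2, 3, 4, 1).reshape(n * do * ho * wo, self.out_ch)
        self.grads["weight"] = (go.T @ flat).reshape(self.params["weight"].shape)
        if "bias" in self.params:
            self.grads["bias"] = go.sum(axis=0)
        w = self.params["weight"]
        gx_pad = np.zeros(pad_shape, dtype=grad_out.dtype)
        sd, sh, sw = self.stride
        go5 = grad_out  # (N, O, Do, Ho, Wo)
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    m = np.tensordot(go5, w[:, :, i, j, l], axes=([1], [0]))
                    # m: (N, Do, Ho, Wo, C) -> (N, C, Do, Ho, Wo)
                    m = m.transpose(0, 4, 1, 2, 3)
                    gx_pad[:, :, i : i + sd * do : sd,
                           j : j + sh * ho : sh,
                           l : l + sw * wo : sw] += m
        sl = tuple(
            slice(p[0], p[0] + d) for p, d in zip(pads, x_shape[2:])
        )
        return gx_pad[:, :, sl[0], sl[1], sl[2]]


class DepthwiseConv3d(Layer):
    """Per-channel 3D convolution (the depthwise half of a separable block)."""

    def __init__(self, ch: int, k: int = 3, stride=(1, 1, 1),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.ch, self.k = ch, k
        self.stride = tuple(stride)
        rng = rng or np.random.default_rng()
        self.params["weight"] = rng.normal(
            0.0, np.sqrt(2.0 / k**3), size=(ch, k, k, k)
        ).astype(np.float32)
        self._cache = None

    def forward(self, x, train=False):
        x_pad, pads = _pad_input(x, self.k, self.stride)
        cols = _window_cols(x_pad, self.k, self.stride)
        out = np.einsum("ncdhwijk,cijk->ncdhw", cols, self.params["weight"],
                        optimize=True)
        if train:
            self._cache = (cols, x.shape, x_pad.shape, pads, out.shape[2:])
        return out

    def backward(self, grad_out):
        cols, x_shape, pad_shape, pads, out_dhw = self._cache
        self.grads["weight"] = np.einsum(
            "ncdhwijk,ncdhw->cijk", cols, grad_out, optimize=True
        )
        w = self.params["weight"]
        gx_pad = np.zeros(pad_shape, dtype=grad_out.dtype)
        sd, sh, sw = self.stride
        do, ho, wo = out_dhw
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    gx_pad[:, :, i : i + sd * do : sd,
                           j : j + sh * ho : sh,
                           l : l + sw * wo : sw] += (
                        grad_out * w[None, :, i, j, l, None, None, None]
                    )
        sl = tuple(slice(p[0], p[0] + d) for p, d in zip(pads, x_shape[2:]))
        return gx_pad[:, :, sl[0], sl[1], sl[2]]


class BatchNorm3d(Layer):
    """Batch normalization over (N, D, H, W) per channel."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.params["gamma"] = np.ones(ch, dtype=np.float32)
        self.params["beta"] = np.zeros(ch, dtype=np.float32)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None

    def forward(self, x, train=False):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        out = (
            self.params["gamma"][None, :, None, None, None] * xhat
            + self.params["beta"][None, :, None, None, None]
        )
        if train:
            self._cache = (xhat, inv, x.shape)
        return out

    def backward(self, grad_out):
        xhat, inv, shape = self._cache
        axes = (0, 2, 3, 4)
        m = shape[0] * shape[2] * shape[3] * shape[4]
        self.grads["gamma"] = (grad_out * xhat).sum(axis=axes)
        self.grads["beta"] = grad_out.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None, None]
        gxhat = grad_out * g
        gx = (
            gxhat
            - gxhat.mean(axis=axes, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv[None, :, None, None, None]
        return gx

    def state(self):
        return {**self.params, "running_mean": self.running_mean,
                "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad_out):
        return grad_out * self._mask


class GlobalAvgPool3d(Layer):
    """Average over all spatio-temporal positions: (N,C,D,H,W) -> (N,C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad_out):
        n, c, d, h, w = self._shape
        return np.broadcast_to(
            grad_out[:, :, None, None, None] / (d * h * w), self._shape
        ).astype(grad_out.dtype)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["weight"] = rng.normal(
            0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim)
        ).astype(np.float32)
        self.params["bias"] = np.zeros(out_dim, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, grad_out):
        self.grads["weight"] = grad_out.T @ self._x
        self.grads["bias"] = grad_out.sum(axis=0)
        return grad_out @ self.params["weight"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss; returns (loss, grad wrt logits, probs)."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype), probs


class Adam:
    """Adam optimizer over a flat name->array parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k].astype(p.dtype)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
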