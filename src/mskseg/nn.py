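"""Minimal CPU neural-network layers with hand-written backpropagation.

Implements exactly the building blocks the 2D Bayesian U-Net needs:
3x3 same-padding convolution, batch normalization, ReLU, elementwise
dropout (kept active at inference for Monte-Carlo sampling), 2x2 max
pooling and 2x2 stride-2 transposed convolution, plus a fused
softmax/cross-entropy head and an Adam optimizer.

All tensors are float32 with layout (N, C, H, W). Convolutions are
evaluated as im2col + GEMM so the heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "MaxPool2d",
    "ConvTranspose2d",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base class: parameters live in ``params``/``grads`` dicts keyed alike."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray, *, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*9) patches of a zero-padded 3x3 neighbourhood."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    # -> (N,H,W,C,3,3) -> (N*H*W, C*9)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = _he_init(rng, (c_out, c_in, 3, 3), fan_in=c_in * 9)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, *, training, rng=None):
        n, c, h, w = x.shape
        cols = _im2col3(x)
        self._cache = (cols, x.shape)
        wmat = self.params["W"].reshape(self.c_out, c * 9)
        out = cols @ wmat.T + self.params["b"]
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gy):
        cols, (n, c, h, w) = self._cache
        gmat = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(n * h * w, self.c_out)
        self.grads["W"] = (gmat.T @ cols).reshape(self.c_out, c, 3, 3)
        self.grads["b"] = gmat.sum(axis=0)
        # dx: full correlation of gy with the spatially flipped, channel-swapped kernel
        wflip = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin,Cout,3,3)
        gcols = _im2col3(gy)
        dx = gcols @ wflip.reshape(self.c_in, self.c_out * 9).T
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x, *, training, rng=None):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, gy):
        xhat, inv = self._cache
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = gy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        sum_gy = gy.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, -1, 1, 1)
        sum_gyx = (gy * xhat).sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, -1, 1, 1)
        return (g * inv[None, :, None, None] / m) * (m * gy - sum_gy - xhat * sum_gyx)


class ReLU(Layer):
    def forward(self, x, *, training, rng=None):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, gy):
        return gy * self._mask


class Dropout(Layer):
    """Inverted dropout; drawn from the caller-supplied RNG when ``active``.

    Unlike the other layers, dropout may stay stochastic outside training:
    Monte-Carlo dropout sampling re-enables it at inference time.
    """

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 < p < 1.0:
            raise ValueError(f"dropout rate must be in (0,1), got {p}")
        self.p = p
        self.active = True  # honoured in addition to the `training` flag

    def forward(self, x, *, training, rng=None):
        if not self.active or rng is None:
            self._mask = None
            return x
        keep = 1.0 - self.p
        mask = (rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32) / keep
        if training:
            self._mask = mask
        return x * mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; even spatial dims required."""

    def forward(self, x, *, training, rng=None):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return out

    def backward(self, gy):
        idx, (n, c, h, w) = self._cache
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gr, idx[..., None], gy[..., None], axis=-1)
        return gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (resolution doubling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = _he_init(rng, (c_in, c_out, 2, 2), fan_in=c_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, *, training, rng=None):
        n, c, h, w = x.shape
        if training:
            self._cache = x
        out = np.einsum("ncij,cokl->noikjl", x, self.params["W"], optimize=True)
        out = out.reshape(n, self.c_out, 2 * h, 2 * w)
        return out + self.params["b"][None, :, None, None]

    def backward(self, gy):
        x = self._cache
        n, co, h2, w2 = gy.shape
        g = gy.reshape(n, co, h2 // 2, 2, w2 // 2, 2)  # (n,o,i,k,j,l)
        self.grads["W"] = np.einsum("ncij,noikjl->cokl", x, g, optimize=True)
        self.grads["b"] = gy.sum(axis=(0, 2, 3))
        return np.einsum("noikjl,cokl->ncij", g, self.params["W"], optimize=True)


class Conv2d1x1(Layer):
    """1x1 convolution — the per-pixel linear classification head."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = _he_init(rng, (c_out, c_in), fan_in=c_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, *, training, rng=None):
        n, c, h, w = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(-1, c)
        if training:
            self._cache = (flat, x.shape)
        out = flat @ self.params["W"].T + self.params["b"]
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gy):
        flat, (n, c, h, w) = self._cache
        g = gy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads["W"] = g.T @ flat
        self.grads["b"] = g.sum(axis=0)
        return (g @ self.params["W"]).reshape(n, h, w, c).transpose(0, 3, 1, 2)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, target: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy; returns (loss, dlogits).

    ``logits``: (N, K, H, W); ``target``: (N, H, W) integer classes.
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    flat_p = p.transpose(0, 2, 3, 1).reshape(-1, k)
    t = target.reshape(-1)
    picked = np.clip(flat_p[np.arange(t.size), t], 1e-12, None)
    if class_weights is None:
        wts = np.ones(t.size, dtype=np.float32)
    else:
        wts = class_weights[t].astype(np.float32)
    wsum = wts.sum()
    loss = float(-(wts * np.log(picked)).sum() / wsum)
    grad = flat_p
    grad[np.arange(t.size), t] -= 1.0
    grad *= (wts / wsum)[:, None]
    return loss, grad.reshape(n, h, w, k).transpose(0, 3, 1, 2).astype(np.float32)


class Adam:
    """Adam over a list of layers (updates every entry of layer.params)."""

    def __init__(self, layers, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / c1) / (np.sqrt(v[k] / c2) + self.eps)
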