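"""Minimal numpy neural-network engine for the reference segmentation net.

Implements exactly what the compact encoder-decoder needs: same-padding
convolutions, ReLU, instance normalization, 2x2 max pooling,
nearest-neighbour upsampling, stable sigmoid/BCE, an Adam optimizer and
the cosine-annealing-with-warm-restarts learning-rate schedule.

Arrays are float32 channels-last (N, H, W, C).  A k x k convolution is
computed as k^2 shifted 1x1 convolutions (one GEMM per tap), which keeps
every operand contiguous and is markedly faster in numpy than an
im2col formulation.  This is deliberately not a general autodiff
framework: each layer caches what its hand-written backward pass needs,
and the network wires forward/backward explicitly.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Conv2d",
    "InstanceNorm",
    "relu",
    "relu_backward",
    "maxpool2",
    "maxpool2_backward",
    "upsample2",
    "upsample2_backward",
    "sigmoid",
    "bce_with_logits",
    "Adam",
    "cosine_warm_restart_lr",
]


class Conv2d:
    """Same-padding convolution with odd kernel size, stride 1, He init.

    Weights have shape (k*k, C_in, C_out): one 1x1 kernel per spatial
    tap, applied to the correspondingly shifted input.
    """

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        assert ksize % 2 == 1
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        fan_in = c_in * ksize * ksize
        scale = math.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, scale, (ksize * ksize, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.ksize
        if k == 1:
            y = x.reshape(-1, c) @ self.W[0] + self.b
            self._cache = (x, None)
            return y.reshape(n, h, w, self.c_out)
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        y = np.tile(self.b, (n * h * w, 1))
        for i in range(k):
            for j in range(k):
                sl = np.ascontiguousarray(xp[:, i:i + h, j:j + w, :]).reshape(-1, c)
                y += sl @ self.W[i * k + j]
        self._cache = (x, xp)
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, xp = self._cache
        n, h, w, c = x.shape
        k = self.ksize
        dyf = dy.reshape(-1, self.c_out)
        self.db = dyf.sum(axis=0)
        if k == 1:
            self.dW = x.reshape(-1, c).T @ dyf
            self.dW = self.dW[None]
            self._cache = None
            return (dyf @ self.W[0].T).reshape(n, h, w, c)
        pad = k // 2
        self.dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = np.ascontiguousarray(xp[:, i:i + h, j:j + w, :]).reshape(-1, c)
                self.dW[i * k + j] = sl.T @ dyf
                dxp[:, i:i + h, j:j + w, :] += (dyf @ self.W[i * k + j].T).reshape(n, h, w, c)
        self._cache = None
        return dxp[:, pad:pad + h, pad:pad + w, :]


class InstanceNorm:
    """Per-sample, per-channel normalization with learned scale/shift.

    Deterministic at inference (no running statistics), which keeps
    training reproducible and the predictor contract simple.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.W = np.ones(channels, dtype=np.float32)   # gamma
        self.b = np.zeros(channels, dtype=np.float32)  # beta
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.eps = eps
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.W * xhat + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.dW = (dy * xhat).sum(axis=(0, 1, 2))
        self.db = dy.sum(axis=(0, 1, 2))
        m1 = dy.mean(axis=(1, 2), keepdims=True)
        m2 = (dy * xhat).mean(axis=(1, 2), keepdims=True)
        self._cache = None
        return self.W * inv * (dy - m1 - xhat * m2)


def relu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = x > 0
    return x * mask, mask


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns pooled values and the argmax index (0..3)."""
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2_backward(dy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    n, hh, wh, c = dy.shape
    d4 = np.zeros((n, hh, wh, c, 4), dtype=dy.dtype)
    np.put_along_axis(d4, idx[..., None], dy[..., None], axis=-1)
    d4 = d4.reshape(n, hh, wh, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return d4.reshape(n, hh * 2, wh * 2, c)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour x2 upsampling."""
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    # log(1 + exp(z)) computed stably
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    loss = float((softplus - target * z).mean())
    dz = (sigmoid(z) - target) / z.size
    return loss, dz.astype(np.float32)


class Adam:
    """Adam over a list of layers exposing W/b and dW/db."""

    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if hasattr(l, "W")]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]
        self._v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for layer, (mW, mb), (vW, vb) in zip(self.layers, self._m, self._v):
            for param, grad, m, v in ((layer.W, layer.dW, mW, vW),
                                      (layer.b, layer.db, mb, vb)):
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                param -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def cosine_warm_restart_lr(epoch: int, lr_max: float, t0: int = 10,
                           t_mult: int = 2, eta_min: float = 0.0) -> float:
    """Learning rate at a (0-based) epoch under warm cosine restarts.

    The rate decays from ``lr_max`` to ``eta_min`` over a cycle of length
    T_i, then restarts; cycle lengths are T0, T0*Tmult, T0*Tmult^2, ...,
    so with T0=10, Tmult=2 the restarts fall at epochs 10 and 30.
    """
    t, ti = epoch, t0
    while t >= ti:
        t -= ti
        ti *= t_mult
    return eta_min + 0.5 * (lr_max - eta_min) * (1.0 + math.cos(math.pi * t / ti))
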