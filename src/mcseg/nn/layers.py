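"""Minimal NumPy layer zoo with analytic backprop.

Implements exactly what the patch classifiers need: 3x3 stride-1
convolutions (same/valid), 2x2 max-pooling, batch normalization with
running statistics, ReLU, inverted dropout and dense layers, all in
float32 by default.  Convolutions run as im2col + matmul; the input
gradient is computed as a transposed convolution (full correlation with
spatially flipped kernels), so every heavy operation is a BLAS matmul.

Each layer caches what its backward pass needs; ``backward`` must follow
the corresponding ``forward``.  Parameters and their gradients are exposed
as aligned lists of arrays that the optimizer updates in place.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, Ho, Wo, C*k*k) patch matrix for stride-1 conv."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # windows: (B, C, Ho, Wo, k, k)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5)
    b, ho, wo = cols.shape[:3]
    return np.ascontiguousarray(cols).reshape(b, ho, wo, -1)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 stride-1 convolution, padding 'same' (1 px) or 'valid' (none)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        padding: str,
        rng: np.random.Generator,
        kernel: int = 3,
        dtype=np.float32,
    ):
        super().__init__()
        self.k = kernel
        self.pad = (kernel - 1) // 2 if padding == "same" else 0
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * kernel * kernel
        # He initialization: zero-mean normal, std sqrt(2 / fan_in)
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None

    def forward(self, x, train, rng=None):
        self._cols = _im2col(x, self.k, self.pad)
        b, ho, wo, _ = self._cols.shape
        out = self._cols.reshape(-1, self._cols.shape[-1]) @ self.w + self.b
        return out.reshape(b, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout):
        b, f, ho, wo = dout.shape
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, f)
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads[0][...] = cols2.T @ d2
        self.grads[1][...] = d2.sum(axis=0)
        # input gradient: full correlation of dout with flipped kernels
        w4 = self.w.reshape(self.in_channels, self.k, self.k, self.out_channels)
        w_flip = w4[:, ::-1, ::-1, :]                      # (C, k, k, F)
        wt = np.ascontiguousarray(w_flip.transpose(3, 1, 2, 0)).reshape(
            self.out_channels * self.k * self.k, self.in_channels
        )
        dcols = _im2col(dout, self.k, self.k - 1 - self.pad)
        dx = dcols.reshape(-1, dcols.shape[-1]) @ wt
        hi, wi = dcols.shape[1], dcols.shape[2]
        self._cols = None
        return dx.reshape(b, hi, wi, self.in_channels).transpose(0, 3, 1, 2)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, floor division on odd sides."""

    def forward(self, x, train, rng=None):
        b, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        if ho < 1 or wo < 1:
            raise ValueError("max-pool input side must be >= 2")
        self._in_shape = x.shape
        xc = x[:, :, : 2 * ho, : 2 * wo]
        r = xc.reshape(b, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, 4)
        self._idx = r.argmax(axis=-1)
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        b, c, ho, wo = dout.shape
        dr = np.zeros((b, c, ho, wo, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        dxc = dr.reshape(b, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, 2 * ho, 2 * wo)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : 2 * ho, : 2 * wo] = dxc
        return dx


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics.

    ``spatial=True`` normalizes (B, C, H, W) over (B, H, W); otherwise a
    dense activation (B, D) over the batch axis.  Training uses batch
    statistics; inference the exponential running averages.
    """

    def __init__(self, channels: int, spatial: bool, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.spatial = spatial
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def _axes(self) -> tuple[int, ...]:
        return (0, 2, 3) if self.spatial else (0,)

    def _shape(self, x) -> tuple[int, ...]:
        return (1, -1, 1, 1) if self.spatial else (1, -1)

    def forward(self, x, train, rng=None):
        axes, sh = self._axes(), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(sh)) / self._std.reshape(sh)
        return self.gamma.reshape(sh) * self._xhat + self.beta.reshape(sh)

    def backward(self, dout):
        axes, sh = self._axes(), self._shape(dout)
        m = np.prod([dout.shape[a] for a in axes])
        self.grads[0][...] = (dout * self._xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        g = self.gamma.reshape(sh) / self._std.reshape(sh)
        dx = g * (
            dout
            - dout.mean(axis=axes).reshape(sh)
            - self._xhat * (dout * self._xhat).sum(axis=axes).reshape(sh) / m
        )
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features)).astype(dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Adam:
    """Adam optimizer updating parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
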