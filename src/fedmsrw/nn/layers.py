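"""Layer primitives with explicit forward/backward passes.

Shapes follow the (N, C, D, H, W) convention.  Each layer keeps its
trainable arrays in ``params``, non-trainable state in ``buffers`` and the
last backward's gradients in ``grads``; a container assembles these into
flat name->array maps.  All compute is float32; convolutions are lowered
to matrix products via im2col so the heavy lifting lands in BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3-D convolution, stride 1, 'same' padding for odd kernels."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.pad = (kernel_size - 1) // 2
        fan_in = in_channels * kernel_size**3
        # He initialisation for ReLU-coupled convs
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, *(kernel_size,) * 3))
        self.params["weight"] = w.astype(np.float32)
        self.params["bias"] = np.zeros(out_channels, dtype=np.float32)
        self._cols: np.ndarray | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, pad = self.k, self.pad
        if pad:
            x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        # (N, C, D, H, W, k, k, k) -> (N*D*H*W, C*k^3)
        n, c, d, h, w = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, c * k**3)
        return np.ascontiguousarray(cols)

    def forward(self, x, training):
        self._xshape = x.shape
        cols = self._im2col(x)
        self._cols = cols if training else None
        w = self.params["weight"].reshape(self.cout, -1)
        out = cols @ w.T + self.params["bias"]
        n, _, d, h, wd = x.shape
        return out.reshape(n, d, h, wd, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, dy):
        n, _, d, h, w = dy.shape
        dy_cols = dy.transpose(0, 2, 3, 4, 1).reshape(-1, self.cout)
        self.grads["weight"] = (
            (dy_cols.T @ self._cols).reshape(self.params["weight"].shape)
        )
        self.grads["bias"] = dy_cols.sum(axis=0)
        # full correlation with the flipped kernel gives dL/dx
        k = self.k
        wflip = self.params["weight"][:, :, ::-1, ::-1, ::-1]
        wback = wflip.transpose(0, 2, 3, 4, 1).reshape(self.cout * k**3, self.cin)
        full_pad = k - 1 - self.pad
        dyp = dy
        if full_pad:
            dyp = np.pad(dy, ((0, 0), (0, 0)) + ((full_pad, full_pad),) * 3)
        win = sliding_window_view(dyp, (k, k, k), axis=(2, 3, 4))
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(-1, self.cout * k**3)
        dx = (np.ascontiguousarray(cols) @ wback).reshape(n, d, h, w, self.cin)
        self._cols = None
        return np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3))


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W).

    Running mean/variance are buffers: client-local state that federated
    aggregation must be able to leave untouched.  Biased variance is used
    both in-batch and for the running estimate.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["weight"] = np.ones(channels, dtype=np.float32)
        self.params["bias"] = np.zeros(channels, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self.buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x, training):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = (
                (1 - m) * self.buffers["running_mean"] + m * mean
            ).astype(np.float32)
            self.buffers["running_var"] = (
                (1 - m) * self.buffers["running_var"] + m * var
            ).astype(np.float32)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        shape = (1, -1, 1, 1, 1)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (xhat, inv_std, training)
        return self.params["weight"].reshape(shape) * xhat + self.params["bias"].reshape(shape)

    def backward(self, dy):
        xhat, inv_std, training = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.grads["weight"] = (dy * xhat).sum(axis=axes)
        self.grads["bias"] = dy.sum(axis=axes)
        dxhat = dy * self.params["weight"].reshape(shape)
        if not training:
            return dxhat * inv_std.reshape(shape)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        ) * inv_std.reshape(shape)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x, training):
        # clip logits so exp never overflows; saturation is unaffected
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -80.0, 80.0)))
        return self._y

    def backward(self, dy):
        return (dy * self._y * (1.0 - self._y)).astype(np.float32)


class MaxPool3d(Layer):
    """2x2x2 max pooling; spatial extents must be even."""

    def forward(self, x, training):
        n, c, d, h, w = x.shape
        blocks = (
            x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, d // 2, h // 2, w // 2, 8)
        )
        self._argmax = blocks.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(blocks, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, d, h, w = self._inshape
        blocks = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(blocks, self._argmax[..., None], dy[..., None], axis=-1)
        return (
            blocks.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, d, h, w)
        )


class Upsample3d(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, training):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy):
        n, c, d, h, w = dy.shape
        return (
            dy.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
            .sum(axis=(3, 5, 7))
            .astype(np.float32)
        )
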