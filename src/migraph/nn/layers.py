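"""Trainable layers on NHWC numpy arrays.

Convolution is im2col + GEMM: patches are gathered with
``sliding_window_view`` (then strided), flattened to a matrix and
multiplied by the flattened kernel bank.  Backward reverses the GEMM;
input gradients are scattered back with a small loop over kernel offsets
(col2im), and are skipped entirely for first layers.  Weight init is
Glorot-uniform from a caller-supplied generator so runs are reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "MaxPool2D", "Flatten", "Dropout", "Dense"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray | None:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid 2-D convolution, optional ReLU fused in."""

    def __init__(self, kernel, filters, stride, in_channels, activation, rng,
                 dtype=np.float32, need_input_grad=True):
        super().__init__()
        self.kh, self.kw = kernel
        self.sh, self.sw = stride
        self.filters = filters
        self.cin = in_channels
        self.activation = activation
        self.dtype = dtype
        self.need_input_grad = need_input_grad
        K = self.kh * self.kw * in_channels
        self.W = _glorot(rng, K, filters, (K, filters), dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (N, H, W, C) -> (N, OH, OW, kh*kw*C), K ordered as (kh, kw, C)
        win = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        win = win[:, :: self.sh, :: self.sw]  # (N, OH, OW, C, kh, kw)
        n, oh, ow = win.shape[:3]
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n, oh, ow, self.kh * self.kw * self.cin
        )

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        self._xshape = x.shape
        patches = self._im2col(x)
        n, oh, ow, K = patches.shape
        out = patches.reshape(-1, K) @ self.W + self.b
        out = out.reshape(n, oh, ow, self.filters)
        if self.activation == "relu":
            self._mask = out > 0
            out = np.maximum(out, 0.0)
        self._patches = patches if train else None
        return out

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._mask
        n, oh, ow, F = dout.shape
        K = self._patches.shape[-1]
        dflat = dout.reshape(-1, F)
        self.grads[0][...] = self._patches.reshape(-1, K).T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        if not self.need_input_grad:
            self._patches = None
            return None
        dpatch = (dflat @ self.W.T).reshape(n, oh, ow, self.kh, self.kw, self.cin)
        dx = np.zeros(self._xshape, dtype=self.dtype)
        for p in range(self.kh):
            for q in range(self.kw):
                dx[:, p : p + self.sh * oh : self.sh, q : q + self.sw * ow : self.sw, :] += dpatch[
                    :, :, :, p, q, :
                ]
        self._patches = None
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling (stride = pool size); trailing rows/cols
    that do not fill a window are dropped, matching floor-division shapes."""

    def __init__(self, pool):
        super().__init__()
        self.ph, self.pw = pool

    def forward(self, x, train):
        n, H, W, C = x.shape
        oh, ow = H // self.ph, W // self.pw
        self._in_shape = x.shape
        xr = x[:, : oh * self.ph, : ow * self.pw, :]
        xr = xr.reshape(n, oh, self.ph, ow, self.pw, C).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, oh, ow, self.ph * self.pw, C)
        self._argmax = xr.argmax(axis=3)
        out = np.take_along_axis(xr, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        return out

    def backward(self, dout):
        n, oh, ow, C = dout.shape
        dxr = np.zeros((n, oh, ow, self.ph * self.pw, C), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dxr = dxr.reshape(n, oh, ow, self.ph, self.pw, C).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : oh * self.ph, : ow * self.pw, :] = dxr.reshape(n, oh * self.ph, ow * self.pw, C)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    """Fully connected layer; softmax is applied by the loss, not here."""

    def __init__(self, in_units, units, activation, rng, dtype=np.float32):
        super().__init__()
        self.activation = activation
        self.W = _glorot(rng, in_units, units, (in_units, units), dtype)
        self.b = np.zeros(units, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        out = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = out > 0
            out = np.maximum(out, 0.0)
        return out

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._mask
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T
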