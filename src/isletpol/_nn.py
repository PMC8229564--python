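"""Minimal CPU neural-network primitives (NumPy, manual backprop).

Just enough machinery for a compact U-Net: 2-D convolutions via im2col,
ReLU, 2x2 max pooling, nearest-neighbour upsampling, channel concatenation,
a numerically stable binary cross-entropy on logits, and Adam.  Everything is
deterministic given the seeds handed in; arrays are NCHW float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Upsample2", "bce_with_logits", "sigmoid", "Adam"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy of logits ``z`` against targets ``y``.

    Returns (loss, dloss/dz).  Uses the log1p(exp(-|z|)) form so large logits
    do not overflow.
    """
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.astype(np.float32)


class Conv2D:
    """Same-padding convolution with He-initialised weights."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        self.pad = k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, (c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)
        self._cols = cols
        self._xshape = x.shape
        F = self.W.shape[0]
        out = cols @ self.W.reshape(F, -1).T + self.b
        return np.ascontiguousarray(out.reshape(B, H, W, F).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._xshape
        k, p = self.k, self.pad
        F = self.W.shape[0]
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, F)
        self.dW += (dyf.T @ self._cols).reshape(self.W.shape)
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ self.W.reshape(F, -1)).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(B, C, H // 2, W // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (B, C, H, W)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        d = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(d, self._idx[..., None], dy[..., None].astype(np.float32), axis=-1)
        d = d.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(d).reshape(B, C, H, W)


class Upsample2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        # params: list of (value, grad) array pairs updated in place
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)
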