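"""Minimal numpy neural-network engine for encoder-decoder segmentation.

Implements exactly the operators the segmentation network needs — 2-D
convolution with same padding, 2x2/stride-2 max pooling, 2x2/stride-2
transposed convolution, LeakyReLU, batch normalization, softmax
cross-entropy — each with an explicit backward pass, plus the Adam
optimizer. Convolutions are evaluated as im2col + matrix products so the
heavy lifting happens inside BLAS.

Array layout is NCHW (batch, channels, height, width), float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ConvTranspose2x2",
    "MaxPool2x2",
    "LeakyReLU",
    "BatchNorm2d",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "he_uniform",
]


def he_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """He/Kaiming uniform initialization: U(-sqrt(6/fan_in), +sqrt(6/fan_in))."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix for a same-padded k x k conv."""
    if k == 1:
        n, c, h, w = x.shape
        return x.reshape(n, c, h * w)
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # windows: (N, C, H, W, k, k)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w = x.shape
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * k * k, h * w)


class Conv2d:
    """k x k convolution (cross-correlation) with same padding, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError(f"unsupported kernel size {kernel}")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.W = he_uniform((out_ch, in_ch * kernel * kernel), fan_in, rng)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        col = _im2col(x, self.k)
        y = np.matmul(self.W, col) + self.b[:, None]
        if train:
            self._col, self._shape = col, x.shape
        return y.reshape(n, self.out_ch, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        dyf = dy.reshape(n, self.out_ch, h * w)
        self.dW[...] = np.matmul(dyf, self._col.transpose(0, 2, 1)).sum(axis=0)
        self.db[...] = dyf.sum(axis=(0, 2))
        self._col = None
        if self.k == 1:
            dx = np.matmul(self.W.T, dyf)
            return dx.reshape(self._shape)
        # dL/dx is the same-padded convolution of dy with the spatially
        # flipped kernel, with in/out channel roles swapped.
        wf = self.W.reshape(self.out_ch, self.in_ch, self.k, self.k)
        wt = wf[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.in_ch, -1)
        col_dy = _im2col(dy, self.k)
        dx = np.matmul(wt, col_dy)
        return dx.reshape(self._shape)


class ConvTranspose2x2:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling).

    Kernel 2 with stride 2 tiles the output without overlap, so each output
    pixel is a single matrix product of the input pixel beneath it.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        # stored as (in_ch, out_ch*4) so forward is one matmul
        self.W = he_uniform((in_ch, out_ch * 4), in_ch, rng)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if train:
            self._x = x
        t = np.matmul(self.W.T, x.reshape(n, c, h * w))  # (N, out*4, HW)
        t = t.reshape(n, self.out_ch, 2, 2, h, w).transpose(0, 1, 4, 2, 5, 3)
        y = t.reshape(n, self.out_ch, 2 * h, 2 * w) + self.b[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        n, c, h, w = x.shape
        dyt = dy.reshape(n, self.out_ch, h, 2, w, 2).transpose(0, 1, 3, 5, 2, 4)
        dyt = np.ascontiguousarray(dyt).reshape(n, self.out_ch * 4, h * w)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        xf = x.reshape(n, c, h * w)
        self.dW[...] = np.matmul(xf, dyt.transpose(0, 2, 1)).sum(axis=0)
        dx = np.matmul(self.W, dyt)
        return dx.reshape(n, c, h, w)


class MaxPool2x2:
    """2x2 max pooling with stride 2; ties route the gradient to the first max."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = np.ascontiguousarray(v).reshape(n, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dv = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dv, self._idx[..., None], dy[..., None], axis=-1)
        self._idx = None
        dx = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = float(slope)
        self._mask: np.ndarray | None = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return np.where(mask, dy, self.slope * dy)


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    @property
    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        mean_dy = dy.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dyx = (dy * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (dy - mean_dy - xhat * mean_dyx)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray):
    """Mean pixel-wise cross entropy over softmax channels.

    logits: (N, K, H, W); target: (N, H, W) integer class labels.
    Returns (loss, dlogits).
    """
    p = softmax(logits, axis=1)
    n, k, h, w = logits.shape
    idx = target[:, None, :, :]
    picked = np.take_along_axis(p, idx, axis=1)[:, 0]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    dlogits = p.copy()
    np.put_along_axis(
        dlogits, idx, np.take_along_axis(dlogits, idx, axis=1) - 1.0, axis=1
    )
    dlogits /= n * h * w
    # flush vanishing entries to exact zero: once the model is confident the
    # off-class probabilities underflow toward float32 subnormals, and
    # propagating subnormals through the backward pass is extremely slow on
    # x86; gradients this small are far below Adam's update resolution.
    dlogits[np.abs(dlogits) < 1e-20] = 0.0
    return loss, dlogits


class Adam:
    """Adam optimizer over a list of (param, grad) array pairs (in-place updates)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
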