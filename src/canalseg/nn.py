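"""Minimal NumPy CNN kernel: layers with explicit forward/backward passes.

Implements exactly the operations the nested-U segmentation network needs —
3x3 (optionally dilated) same-padding convolutions via im2col matrix
multiplication, ReLU, 2x2 max pooling, nearest-neighbor 2x upsampling, a
sigmoid/binary-cross-entropy head and an Adam optimizer — all in float32 on
``(N, C, H, W)`` arrays. Gradients are hand-derived and verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvBlock",
    "MaxPool2",
    "Up2",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "soft_dice",
]


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value.astype(np.float32)
        self.g = np.zeros_like(self.v)


def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for same-padding conv."""
    d = dilation
    p = d * (k // 2)
    span = (k - 1) * d + 1
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(2, 3))
    win = win[..., ::d, ::d]  # (N, C, H, W, k, k)
    N, C, H, W = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k)


def _conv_same(x: np.ndarray, W: np.ndarray, dilation: int) -> np.ndarray:
    """Correlate x (N,C,H,W) with W (O,C,k,k), same padding, stride 1."""
    O, C, k, _ = W.shape
    N, _, H, Wd = x.shape
    cols = _im2col(x, k, dilation)
    y = cols @ W.reshape(O, -1).T
    return y.reshape(N, H, Wd, O).transpose(0, 3, 1, 2)


class Conv2d:
    """3x3 (or 1x1) same-padding convolution, stride 1, optional dilation."""

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, (cout, cin, k, k)).astype(np.float32))
        self.b = Param(np.zeros(cout, np.float32))
        self.k = k
        self.dilation = dilation
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = _conv_same(x, self.W.v, self.dilation)
        return y + self.b.v[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        O = self.W.v.shape[0]
        N, _, H, Wd = x.shape
        cols = _im2col(x, self.k, self.dilation)
        gy_mat = gy.transpose(0, 2, 3, 1).reshape(N * H * Wd, O)
        self.W.g += (gy_mat.T @ cols).reshape(self.W.v.shape)
        self.b.g += gy.sum(axis=(0, 2, 3))
        # input gradient = same conv with spatially flipped, channel-swapped kernels
        Wt = self.W.v[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return _conv_same(gy, np.ascontiguousarray(Wt), self.dilation)


class ConvBlock:
    """Conv2d followed by leaky ReLU (the repeated conv unit of the nested U).

    The small negative slope keeps narrow-channel configurations trainable
    without batch normalization (no dead units).
    """

    LEAK = 0.01

    def __init__(self, cin, cout, dilation=1, rng=None):
        self.conv = Conv2d(cin, cout, 3, dilation, rng)
        self._slope: np.ndarray | None = None

    def params(self):
        return self.conv.params()

    def forward(self, x):
        y = self.conv.forward(x)
        self._slope = np.where(y > 0, np.float32(1.0), np.float32(self.LEAK))
        return y * self._slope

    def backward(self, gy):
        return self.conv.backward(gy * self._slope)


class MaxPool2:
    """2x2 max pooling, stride 2; input H, W must be even."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x):
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"max-pool input must have even extents, got {H}x{W}")
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(N, C, H // 2, W // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (N, C, H, W)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        N, C, H, W = self._shape
        g = np.zeros((N, C, H // 2, W // 2, 4), np.float32)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(N, C, H, W)


class Up2:
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        N, C, H, W = gy.shape
        return gy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


def upsample_to(x: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor upsampling by a power-of-two factor (for side outputs)."""
    if factor == 1:
        return x
    return x.repeat(factor, axis=2).repeat(factor, axis=3)


def downsum_from(gy: np.ndarray, factor: int) -> np.ndarray:
    """Adjoint of :func:`upsample_to`."""
    if factor == 1:
        return gy
    N, C, H, W = gy.shape
    return gy.reshape(N, C, H // factor, factor, W // factor, factor).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy from logits; returns (loss, dL/dz)."""
    n = z.size
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / n
    return loss, grad.astype(z.dtype)


def soft_dice(z: np.ndarray, y: np.ndarray, eps: float = 1.0):
    """Soft Dice loss on sigmoid(z); returns (loss, dL/dz)."""
    s = sigmoid(z)
    inter = float((s * y).sum())
    denom = float(s.sum() + y.sum()) + eps
    dice = (2.0 * inter + eps) / denom
    # d/ds of (1 - dice)
    gs = -(2.0 * y * denom - (2.0 * inter + eps)) / (denom**2)
    grad = gs * s * (1.0 - s)
    return 1.0 - dice, grad.astype(z.dtype)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.v = [np.zeros_like(p.v) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.g
            v *= self.beta2
            v += (1 - self.beta2) * p.g**2
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
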