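"""Minimal numpy layer framework with hand-written backpropagation.

Convolutions run as im2col matrix products; every layer caches what its
backward pass needs.  All analytic gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class LRNConfig:
    """Local response normalization constants.

    Each activation is divided by (bias_k + alpha * S)^beta where S is the
    sum of squared activations over a window of ``depth_radius`` adjacent
    feature maps on each side (clipped at the channel boundaries).

    ``bias_k`` defaults to 1 so the layer has near-unity gain at small
    activations; a larger additive constant attenuates every feature map
    by bias_k^-beta even when the squared-activation sum is negligible,
    which compounds across stacked blocks.
    """

    depth_radius: int = 5
    alpha: float = 1e-4
    beta: float = 0.75
    bias_k: float = 1.0

    def validate(self) -> None:
        if self.depth_radius < 1:
            raise ValueError("depth_radius must be >= 1")
        if self.alpha <= 0 or self.bias_k <= 0 or self.beta <= 0:
            raise ValueError("alpha, beta and bias_k must be positive")


# ---------------------------------------------------------------------------
# convolution primitives (same padding, stride 1)

def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray | None = None):
    """x (B,C,H,W) * W (F,C,k,k) -> (out (B,F,H,W), im2col cache)."""
    B, C, H, Wd = x.shape
    F, C2, k, _ = W.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(B * H * Wd, C * k * k)
    out = cols @ W.reshape(F, -1).T  # (B*HW, F)
    if b is not None:
        out = out + b
    out = out.reshape(B, H, Wd, F).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), cols


def conv2d_grad_w(dout: np.ndarray, cols: np.ndarray, kshape) -> np.ndarray:
    """Weight gradient from the cached im2col matrix."""
    F, C, k, _ = kshape
    B = dout.shape[0]
    dmat = dout.transpose(0, 2, 3, 1).reshape(-1, F)  # (B*HW, F)
    return (dmat.T @ cols).reshape(F, C, k, k)


def conv2d_grad_x(dout: np.ndarray, W: np.ndarray, x_shape) -> np.ndarray:
    """Input gradient (fold of the column gradient)."""
    B, C, H, Wd = x_shape
    F, _, k, _ = W.shape
    p = k // 2
    dmat = dout.transpose(0, 2, 3, 1).reshape(-1, F)
    dcols = dmat @ W.reshape(F, -1)  # (B*HW, C*k*k)
    dcols = dcols.reshape(B, H, Wd, C, k, k).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((B, C, H + 2 * p, Wd + 2 * p), dtype=dout.dtype)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + H, dj:dj + Wd] += dcols[:, :, di, dj]
    return dxp[:, :, p:p + H, p:p + Wd]


# ---------------------------------------------------------------------------
# LRN primitives

def _channel_window_sum(x: np.ndarray, radius: int) -> np.ndarray:
    """Per-channel sum over the clipped window [i-radius, i+radius]."""
    cs = np.cumsum(x, axis=1)
    C = x.shape[1]
    out = np.empty_like(x)
    for i in range(C):
        hi = min(C - 1, i + radius)
        lo = i - radius
        out[:, i] = cs[:, hi] - (cs[:, lo - 1] if lo > 0 else 0)
    return out


def lrn_forward(x: np.ndarray, cfg: LRNConfig):
    S = _channel_window_sum(x * x, cfg.depth_radius)
    D = cfg.bias_k + cfg.alpha * S
    Db = D ** (-cfg.beta)
    y = x * Db
    return y, (x, D, Db, y)


def lrn_backward(dout: np.ndarray, cache, cfg: LRNConfig) -> np.ndarray:
    x, D, Db, y = cache
    inner = _channel_window_sum(dout * y / D, cfg.depth_radius)
    return dout * Db - 2.0 * cfg.alpha * cfg.beta * x * inner


# ---------------------------------------------------------------------------
# layers

class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, d: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _uniform_init(shape, fan_in, rng, dtype):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class RCLBlock(Layer):
    """Recurrent convolutional layer unrolled over T steps.

    state_0 = lrn(relu(conv_ff(x) + b))
    state_t = lrn(relu(conv_ff(x) + conv_rec(state_{t-1}) + b)),  t = 1..T

    The feed-forward convolution of the (fixed) input is re-injected at
    every step; only the feed-forward path exists at t = 0.  Gradients for
    the shared feed-forward kernel accumulate across all T+1 injections.
    """

    def __init__(self, cin: int, cout: int, kernel: int = 3, unroll: int = 3,
                 lrn_cfg: LRNConfig | None = None, rng=None,
                 dtype=np.float32):
        if unroll < 0:
            raise ValueError("unroll steps must be >= 0")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.lrn_cfg = lrn_cfg or LRNConfig()
        self.lrn_cfg.validate()
        self.T = unroll
        self.W_ff = _uniform_init((cout, cin, kernel, kernel),
                                  cin * kernel * kernel, rng, dtype)
        self.W_rec = _uniform_init((cout, cout, kernel, kernel),
                                   cout * kernel * kernel, rng, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW_ff = np.zeros_like(self.W_ff)
        self.dW_rec = np.zeros_like(self.W_rec)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W_ff, self.W_rec, self.b]

    def grads(self):
        return [self.dW_ff, self.dW_rec, self.db]

    def forward(self, x, train=False):
        ff, cols_x = conv2d_forward(x, self.W_ff, self.b)
        s = None
        steps = []
        for t in range(self.T + 1):
            if t == 0:
                z = ff
                cols_s = None
            else:
                rec, cols_s = conv2d_forward(s, self.W_rec)
                z = ff + rec
            mask = z > 0
            a = z * mask
            y, lrn_cache = lrn_forward(a, self.lrn_cfg)
            steps.append((cols_s, mask, lrn_cache))
            s = y
        self._cache = (cols_x, x.shape, steps)
        return s

    def backward(self, dout):
        cols_x, x_shape, steps = self._cache
        dW_rec = np.zeros_like(self.W_rec)
        dz_sum = None
        d = dout
        for t in range(self.T, -1, -1):
            cols_s, mask, lrn_cache = steps[t]
            dz = lrn_backward(d, lrn_cache, self.lrn_cfg) * mask
            dz_sum = dz if dz_sum is None else dz_sum + dz
            if t > 0:
                dW_rec += conv2d_grad_w(dz, cols_s, self.W_rec.shape)
                # state shape equals output shape under same padding
                d = conv2d_grad_x(dz, self.W_rec, dout.shape)
        self.dW_ff[...] = conv2d_grad_w(dz_sum, cols_x, self.W_ff.shape)
        self.dW_rec[...] = dW_rec
        self.db[...] = dz_sum.sum(axis=(0, 2, 3))
        return conv2d_grad_x(dz_sum, self.W_ff, x_shape)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (even spatial dims required)."""

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(B, C, H // 2, W // 2, 4)
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape)
        return out

    def backward(self, d):
        arg, (B, C, H, W) = self._cache
        dxr = np.zeros((B, C, H // 2, W // 2, 4), dtype=d.dtype)
        np.put_along_axis(dxr, arg[..., None], d[..., None], axis=-1)
        dx = dxr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(B, C, H, W)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)


class ReLULayer(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, d):
        return d * self._mask


class Dense(Layer):
    def __init__(self, nin, nout, rng=None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = _uniform_init((nin, nout), nin, rng, dtype)
        self.b = np.zeros(nout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, d):
        self.dW[...] = self._x.T @ d
        self.db[...] = d.sum(axis=0)
        return d @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity outside training.  The generator is owned
    by the network so a fixed training seed reproduces the mask sequence."""

    def __init__(self, p: float = 0.5):
        if not (0 <= p < 1):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, d):
        return d if self._mask is None else d * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray):
    """(mean cross-entropy loss, gradient wrt logits)."""
    p = softmax(logits)
    B = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(B), y] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, dlogits / B
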