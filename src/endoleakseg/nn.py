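"""Minimal CPU neural-network kernels for the segmentation model.

Implements exactly what the compact U-net needs — 3×3/1×1 convolutions via
im2col and BLAS matmuls, ReLU, 2×2 max-pool, nearest-neighbour upsampling,
channel concatenation, a sigmoid head with combined binary-cross-entropy +
soft-Dice loss, and Adam — in float32 with hand-written backward passes.
Arrays are (N, C, H, W).  Everything is deterministic given the seeds fed in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2D:
    """k×k same-padding convolution (k odd), He-normal init."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (c_out, c_in, k, k)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    @property
    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x (N,C,H,W) -> (N, H*W, C*k*k)
        n, c, h, w = x.shape
        p = self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        v = sliding_window_view(x, (self.k, self.k), axis=(2, 3))  # (N,C,H,W,k,k)
        return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, h * w, c * self.k * self.k)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        wmat = self.W.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.b
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dy2 = dy.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (N,HW,Co)
        self.dW[...] = np.tensordot(dy2, self._cols,
                                    axes=([0, 1], [0, 1])).reshape(self.W.shape)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        # dx = full correlation of dy with the flipped kernel, summed over c_out
        wflip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, -1)
        p = self.k // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        v = sliding_window_view(dyp, (self.k, self.k), axis=(2, 3))
        colsy = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, h * w, self.c_out * self.k * self.k)
        dx = (colsy @ wflip.T).transpose(0, 2, 1).reshape(n, self.c_in, h, w)
        self._cols = None
        return dx


class ReLU:
    params: list = []

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2:
    """2×2 max-pooling, stride 2; gradient flows to (all) argmax positions."""

    params: list = []

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._x, self._out = xr, out
        return out

    def backward(self, dy):
        mask = self._x == self._out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = mask * (dy[:, :, :, None, :, None] / counts)
        n, c, h2, _, w2, _ = self._x.shape
        return d.reshape(n, c, h2 * 2, w2 * 2)


class Upsample2:
    """Nearest-neighbour ×2 upsampling; gradient sums 2×2 blocks."""

    params: list = []

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_dice_loss(logits: np.ndarray, target: np.ndarray,
                  dice_weight: float = 1.0, eps: float = 1.0
                  ) -> tuple[float, np.ndarray, dict]:
    """Combined mean BCE + (1 − soft Dice) over the whole batch.

    Returns (loss, dLoss/dlogits, parts).  The Dice term is computed over all
    pixels in the batch jointly, which keeps its gradient well-defined for
    all-background targets (eps smoothing).
    """
    p = sigmoid(logits.astype(np.float64))
    t = target.astype(np.float64)
    npix = p.size
    p_c = np.clip(p, 1e-7, 1 - 1e-7)
    bce = float(-(t * np.log(p_c) + (1 - t) * np.log(1 - p_c)).mean())
    dbce_dz = (p - t) / npix

    inter = float((p * t).sum())
    sums = float(p.sum() + t.sum())
    dice = (2 * inter + eps) / (sums + eps)
    # d(dice)/dp = (2t*(sums+eps) - (2*inter+eps)) / (sums+eps)^2
    ddice_dp = (2 * t * (sums + eps) - (2 * inter + eps)) / (sums + eps) ** 2
    ddice_dz = -ddice_dp * p * (1 - p)

    loss = bce + dice_weight * (1.0 - dice)
    dz = (dbce_dz + dice_weight * ddice_dz).astype(F32)
    return loss, dz, {"bce": bce, "dice": float(dice)}


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for _, p, _ in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for _, p, _ in l.params] for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for li, layer in enumerate(self.layers):
            for pi, (_, p, g) in enumerate(layer.params):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
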