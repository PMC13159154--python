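"""Minimal NumPy convolutional network engine for image-to-image regression.

Implements exactly what the in-silico staining task needs — 3×3 "same"
convolutions (im2col + GEMM), ReLU, 2×2 average pooling, nearest-neighbour
upsampling, skip concatenation and a 1×1 output head — with hand-written
backward passes and an Adam optimizer. Arrays are NHWC float32 throughout
(im2col gathers then reduce to k² contiguous slice copies, which is what
keeps the pure-NumPy implementation fast). Initialization and data order
are driven by caller-supplied generators, so training is reproducible
bit-for-bit on one platform.
"""

from __future__ import annotations

import numpy as np


class Conv2D:
    """k×k same-padding convolution (k odd), bias included. NHWC.

    Uses a shift-and-GEMM scheme instead of im2col: for each kernel row the
    full padded-width slab (which is contiguous per sample) feeds one GEMM
    against all k horizontal taps at once, and the k results are accumulated
    with shifted slices. All heavy operations are contiguous matrix products.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 weight_scale: float | None = None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((k, k, cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        cout = self.W.shape[-1]
        if k == 1:
            out = x.reshape(-1, c) @ self.W[0, 0] + self.b
            self._cache = (x, None, x.shape)
            return out.reshape(n, h, w, cout)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        wp = w + 2 * p
        out = np.zeros((n, h, w, cout), dtype=np.float32)
        slabs = []
        for i in range(k):
            # contiguous per-sample slab: rows i..i+h of the padded image
            slab = xp[:, i : i + h, :, :].reshape(n * h * wp, c)
            slabs.append(slab)
            wi = self.W[i].transpose(1, 0, 2).reshape(c, k * cout)  # (cin, k*cout)
            g = (slab @ wi).reshape(n, h, wp, k, cout)
            for j in range(k):
                out += g[:, :, j : j + w, j, :]
        out += self.b
        self._cache = (slabs, wp, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cache, wp, x_shape = self._cache
        n, h, w, c = x_shape
        k, p = self.k, self.k // 2
        cout = self.W.shape[-1]
        dout2 = dout.reshape(n * h * w, cout)
        self.db = dout2.sum(axis=0)
        self._cache = None
        if k == 1:
            x = cache
            self.dW = (x.reshape(-1, c).T @ dout2).reshape(self.W.shape)
            return (dout2 @ self.W[0, 0].T).reshape(n, h, w, c)
        slabs = cache
        self.dW = np.empty_like(self.W)
        dpad = np.zeros((n, h, wp, cout), dtype=np.float32)
        for j in range(k):
            dpad[:] = 0.0
            dpad[:, :, j : j + w, :] = dout
            dflat = dpad.reshape(n * h * wp, cout)
            for i in range(k):
                self.dW[i, j] = slabs[i].T @ dflat
        dxp = np.zeros((n, h + 2 * p, wp, c), dtype=np.float32)
        for i in range(k):
            # per-tap contribution dout @ W[i,j]^T added at its shifted location
            for j in range(k):
                dij = (dout2 @ self.W[i, j].T).reshape(n, h, w, c)
                dxp[:, i : i + h, j : j + w, :] += dij
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out


def _pool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


def _pool2_backward(d: np.ndarray) -> np.ndarray:
    return (np.repeat(np.repeat(d, 2, axis=1), 2, axis=2) / 4.0).astype(np.float32)


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_backward(d: np.ndarray) -> np.ndarray:
    n, h, w, c = d.shape
    return d.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class DoubleConv:
    """(conv3×3 → ReLU) × 2."""

    def __init__(self, cin, cout, rng):
        self.c1, self.r1 = Conv2D(cin, cout, 3, rng), ReLU()
        self.c2, self.r2 = Conv2D(cout, cout, 3, rng), ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dout):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dout))))

    def convs(self):
        return [self.c1, self.c2]


class UNet:
    """Encoder-decoder with skip connections for 2D image translation.

    ``depth`` pooling levels halve resolution each; feature width doubles
    per level from ``base_filters``. Input spatial dims must be divisible by
    ``2**depth`` (the training/inference wrappers pad as needed). Tensors
    are NHWC; in/out have a single channel by default.
    """

    def __init__(self, depth: int = 2, base_filters: int = 16,
                 in_ch: int = 1, out_ch: int = 1,
                 rng: np.random.Generator | None = None):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.base_filters = base_filters
        f = base_filters
        self.enc = []
        cin = in_ch
        for i in range(depth):
            self.enc.append(DoubleConv(cin, f * 2**i, rng))
            cin = f * 2**i
        self.bottleneck = DoubleConv(cin, f * 2**depth, rng)
        self.dec = []
        for i in reversed(range(depth)):
            self.dec.append(DoubleConv(f * 2 ** (i + 1) + f * 2**i, f * 2**i, rng))
        self.head = Conv2D(f, out_ch, 1, rng, weight_scale=np.sqrt(1.0 / f))

    def _convs(self):
        convs = []
        for blk in self.enc:
            convs += blk.convs()
        convs += self.bottleneck.convs()
        for blk in self.dec:
            convs += blk.convs()
        convs.append(self.head)
        return convs

    def params(self):
        out = []
        for c in self._convs():
            out += c.params()
        return out

    def grads(self):
        out = []
        for c in self._convs():
            out += c.grads()
        return out

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            p[...] = w

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.shape[1] % 2**self.depth or x.shape[2] % 2**self.depth:
            raise ValueError(f"spatial dims must be divisible by {2**self.depth}")
        skips = []
        h = x
        for blk in self.enc:
            h = blk.forward(h)
            skips.append(h)
            h = _pool2(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for blk, skip in zip(self.dec, reversed(skips)):
            h = _up2(h)
            self._skip_channels.append((h.shape[-1], skip.shape[-1]))
            h = np.concatenate([h, skip], axis=-1)
            h = blk.forward(h)
        return self.head.forward(h)

    def backward(self, dout: np.ndarray):
        d = self.head.backward(dout)
        dskips = []
        for blk, (c_up, c_skip) in zip(reversed(self.dec), reversed(self._skip_channels)):
            d = blk.backward(d)
            d, dskip = d[..., :c_up], d[..., c_up : c_up + c_skip]
            d = _up2_backward(d)
            dskips.append(dskip)
        d = self.bottleneck.backward(d)
        for blk, dskip in zip(reversed(self.enc), reversed(dskips)):
            d = _pool2_backward(d) + dskip
            d = blk.backward(d)
        return d


class Adam:
    """Adam optimizer over a flat parameter list (in-place updates)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = (pred - target).astype(np.float32)
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size
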