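"""Minimal numpy neural-network kernels for the desk-scale diffusion trainer.

Implements exactly what the trainer needs — 3x3 same-padding convolutions
with im2col forward/backward, ReLU, inverted dropout, AdamW with decoupled
weight decay, and an EMA shadow of the weights — with every source of
randomness drawn from explicit generators.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

_OFFSETS = [(dr, dc) for dr in range(3) for dc in range(3)]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, C*9, H*W) patches of the zero-padded input."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((b, c, 9, h, w), dtype=x.dtype)
    for k, (dr, dc) in enumerate(_OFFSETS):
        cols[:, :, k] = xp[:, :, dr : dr + h, dc : dc + w]
    return cols.reshape(b, c * 9, h * w)


def _col2im(gcols: np.ndarray, shape: Tuple[int, int, int, int]) -> np.ndarray:
    b, c, h, w = shape
    g = gcols.reshape(b, c, 9, h, w)
    gxp = np.zeros((b, c, h + 2, w + 2), dtype=gcols.dtype)
    for k, (dr, dc) in enumerate(_OFFSETS):
        gxp[:, :, dr : dr + h, dc : dc + w] += g[:, :, k]
    return gxp[:, :, 1:-1, 1:-1]


class Conv3x3:
    """3x3 convolution, stride 1, zero same-padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.weight = rng.normal(0.0, scale, size=(c_out, c_in * 9))
        self.bias = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray):
        cols = _im2col(x)
        y = np.einsum("oi,bip->bop", self.weight, cols)
        y += self.bias[None, :, None]
        b, _, h, w = x.shape
        return y.reshape(b, self.c_out, h, w), (cols, x.shape)

    def backward(self, gy: np.ndarray, cache):
        cols, xshape = cache
        b, _, h, w = xshape
        g = gy.reshape(b, self.c_out, h * w)
        gw = np.einsum("bop,bip->oi", g, cols)
        gb = g.sum(axis=(0, 2))
        gcols = np.einsum("oi,bop->bip", self.weight, g)
        return _col2im(gcols, xshape), gw, gb


class NoisePredictor:
    """Small convolutional epsilon-predictor.

    The noisy image is concatenated with four constant timestep-embedding
    channels (t/T and low-frequency sinusoids); three 3x3 conv layers with
    ReLU and optional dropout map it to the predicted noise.
    """

    N_TIME_CHANNELS = 4

    def __init__(self, channels: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv1 = Conv3x3(1 + self.N_TIME_CHANNELS, channels, rng)
        self.conv2 = Conv3x3(channels, channels, rng)
        self.conv3 = Conv3x3(channels, 1, rng)
        self.channels = channels

    # -- parameter plumbing -------------------------------------------------
    @property
    def layers(self):
        return [self.conv1, self.conv2, self.conv3]

    def get_params(self) -> List[np.ndarray]:
        out = []
        for lay in self.layers:
            out += [lay.weight, lay.bias]
        return out

    def set_params(self, params: List[np.ndarray]) -> None:
        it = iter(params)
        for lay in self.layers:
            lay.weight = next(it).copy()
            lay.bias = next(it).copy()

    # -- forward / backward -------------------------------------------------
    def _time_embed(self, t_frac: np.ndarray, h: int, w: int) -> np.ndarray:
        t = np.asarray(t_frac, dtype=np.float64).reshape(-1, 1)
        feats = np.concatenate(
            [t, np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), np.sin(4 * np.pi * t)],
            axis=1,
        )
        return np.broadcast_to(feats[:, :, None, None], (t.shape[0], 4, h, w))

    def forward(
        self,
        x: np.ndarray,
        t_frac: np.ndarray,
        dropout: float = 0.0,
        rng: Optional[np.random.Generator] = None,
    ):
        """x: (B, H, W) noisy images; t_frac: (B,) timestep fractions t/T."""
        b, h, w = x.shape
        inp = np.concatenate(
            [x[:, None], self._time_embed(t_frac, h, w)], axis=1
        )
        y1, c1 = self.conv1.forward(inp)
        a1 = np.maximum(y1, 0.0)
        y2, c2 = self.conv2.forward(a1)
        a2 = np.maximum(y2, 0.0)
        if dropout > 0.0:
            if rng is None:
                raise ValueError("dropout requires an rng")
            keep = (rng.random(a2.shape) >= dropout) / (1.0 - dropout)
            a2 = a2 * keep
        else:
            keep = None
        y3, c3 = self.conv3.forward(a2)
        cache = (c1, y1, c2, y2, keep, c3)
        return y3[:, 0], cache

    def backward(self, g_out: np.ndarray, cache) -> List[np.ndarray]:
        """Gradient of a scalar loss w.r.t. all parameters, given dL/d eps_hat."""
        c1, y1, c2, y2, keep, c3 = cache
        g = g_out[:, None]
        g_a2, gw3, gb3 = self.conv3.backward(g, c3)
        if keep is not None:
            g_a2 = g_a2 * keep
        g_y2 = g_a2 * (y2 > 0)
        g_a1, gw2, gb2 = self.conv2.backward(g_y2, c2)
        g_y1 = g_a1 * (y1 > 0)
        _, gw1, gb1 = self.conv1.backward(g_y1, c1)
        return [gw1, gb1, gw2, gb2, gw3, gb3]


class AdamW:
    """Adam with decoupled weight decay and linear learning-rate warmup."""

    def __init__(
        self,
        params: List[np.ndarray],
        lr: float = 1e-4,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
        warmup_steps: int = 0,
    ):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.warmup_steps = warmup_steps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        lr = self.lr
        if self.warmup_steps > 0:
            lr *= min(1.0, self.t / self.warmup_steps)
        b1, b2 = self.betas
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps))
            if p.ndim > 1 and self.weight_decay > 0:  # decay weights, not biases
                p -= lr * self.weight_decay * p


class EMA:
    """Exponential moving average shadow of the parameters.

    Uses the standard warmup rule decay_t = min(decay, (1+t)/(10+t)) so the
    shadow tracks the raw weights early in training instead of anchoring to
    the random initialization, approaching the configured decay asymptotically.
    """

    def __init__(self, params: List[np.ndarray], decay: float = 0.9999):
        self.decay = decay
        self.shadow = [p.copy() for p in params]
        self.t = 0

    def update(self, params: List[np.ndarray]) -> None:
        self.t += 1
        d = min(self.decay, (1 + self.t) / (10 + self.t))
        for s, p in zip(self.shadow, params):
            s *= d
            s += (1 - d) * p
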