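"""Desk-scale denoising-diffusion trainer with the bio-inspired composite loss.

The forward process is the standard Gaussian Markov chain
q(z_t | z_{t-1}) = N(sqrt(1-beta_t) z_{t-1}, beta_t I) under a squared-cosine
noise schedule; a small convolutional network predicts the added noise
(epsilon-objective) and the training loss is

    L_total = L_diffusion + lambda_GAPI * L_GAPI + lambda_DTBR * L_DTBR

with the GAPI and DTBR losses evaluated in image space on the predicted clean
image x0_hat (their definitions are written over pixel intensities, so latent-
space application would be unfaithful). Inpainting samples run the learned
reverse chain while re-imposing the known pixels at every step by forward-
diffusing them to the current timestep (mask-replacement conditioning).

Paper-scale hyperparameters (T=1000, 512x512, batch 16, AdamW 1e-4, EMA
0.9999, warmup 1000, grad accumulation 4, dropout 0.1) are the documented
defaults of :class:`DiffusionConfig`; :meth:`DiffusionConfig.desk` is the
small profile used by the tests (32x32 pixel space, T=200).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import dtbr as _dtbr
from . import gapi as _gapi
from .nn import EMA, AdamW, NoisePredictor
from .phantom import Phantom


@dataclass(frozen=True)
class NoiseSchedule:
    """Variance schedule beta_1..beta_T with cumulative products alpha_bar_t."""

    T_steps: int
    betas: np.ndarray
    alpha_bars: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.betas, dtype=float)
        ab = np.asarray(self.alpha_bars, dtype=float)
        if len(b) != self.T_steps or len(ab) != self.T_steps:
            raise ValueError("betas and alpha_bars must have length T_steps")
        if (b <= 0).any() or (b > 0.999).any():
            raise ValueError("betas must lie strictly within (0, 0.999]")
        if (np.diff(ab) >= 0).any() or (ab <= 0).any() or (ab >= 1).any():
            raise ValueError("alpha_bars must be strictly decreasing in (0, 1)")

    def alpha_bar(self, t: int) -> float:
        """alpha_bar_t with the convention alpha_bar_0 = 1."""
        if t == 0:
            return 1.0
        return float(self.alpha_bars[t - 1])


def cosine_schedule(T_steps: int, s: float = 0.008, max_beta: float = 0.999) -> NoiseSchedule:
    """Squared-cosine alpha_bar construction with offset ``s``, beta-clipped."""
    if T_steps < 2:
        raise ValueError("T_steps must be >= 2")
    t = np.arange(T_steps + 1, dtype=float)
    f = np.cos(((t / T_steps + s) / (1.0 + s)) * np.pi / 2.0) ** 2
    ab_raw = f / f[0]
    betas = np.clip(1.0 - ab_raw[1:] / ab_raw[:-1], 1e-8, max_beta)
    alpha_bars = np.cumprod(1.0 - betas)
    return NoiseSchedule(T_steps=T_steps, betas=betas, alpha_bars=alpha_bars)


@dataclass(frozen=True)
class DiffusionConfig:
    """Trainer hyperparameters (defaults are the paper-scale profile)."""

    lambda_gapi: float = 0.8
    lambda_dtbr: float = 0.6
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    warmup_steps: int = 1000
    ema_decay: float = 0.9999
    dropout: float = 0.1
    batch_size: int = 16
    grad_accum: int = 4
    epochs: int = 100
    image_size: int = 512
    latent_shape: Tuple[int, int, int] = (4, 64, 64)
    T_steps: int = 1000
    seed: int = 0
    channels: int = 16

    def __post_init__(self):
        if self.lambda_gapi < 0 or self.lambda_dtbr < 0:
            raise ValueError("lambda_gapi and lambda_dtbr must be >= 0")

    @classmethod
    def desk(cls, **overrides) -> "DiffusionConfig":
        """Small pixel-space profile: 32x32, T=200, fast warmup."""
        base = dict(
            learning_rate=3e-3,
            warmup_steps=20,
            ema_decay=0.99,
            epochs=1,
            image_size=32,
            latent_shape=(1, 32, 32),
            T_steps=200,
        )
        base.update(overrides)
        return cls(**base)


def forward_diffuse(
    z0: np.ndarray, t: int, schedule: NoiseSchedule, noise: np.ndarray
) -> np.ndarray:
    """Closed-form marginal z_t = sqrt(ab_t) z_0 + sqrt(1 - ab_t) eps."""
    if not (1 <= t <= schedule.T_steps):
        raise ValueError(f"t must be in [1, {schedule.T_steps}], got {t}")
    ab = schedule.alpha_bar(t)
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * noise


def predict_x0(
    zt: np.ndarray, predicted_noise: np.ndarray, t: int, schedule: NoiseSchedule
) -> np.ndarray:
    """Algebraic inversion of the forward marginal given the predicted noise."""
    if not (1 <= t <= schedule.T_steps):
        raise ValueError(f"t must be in [1, {schedule.T_steps}], got {t}")
    ab = schedule.alpha_bar(t)
    return (zt - np.sqrt(1.0 - ab) * predicted_noise) / np.sqrt(ab)


def composite_loss(
    x0_batch: np.ndarray,
    x0_hat_batch: np.ndarray,
    masks: Optional[np.ndarray],
    class_maps: np.ndarray,
    stages: Sequence[int],
    noise: np.ndarray,
    noise_hat: np.ndarray,
    config: DiffusionConfig = DiffusionConfig(),
    gapi_params: _gapi.GapiParams = _gapi.GapiParams(),
    dtbr_params: _dtbr.DtbrParams = _dtbr.DtbrParams(),
) -> Tuple[float, Dict[str, float]]:
    """L_total = L_diffusion + lambda_GAPI * L_GAPI + lambda_DTBR * L_DTBR.

    L_diffusion is the epsilon-prediction MSE; the bio losses average their
    per-image values over the batch and see the whole image (``masks`` is
    accepted for interface completeness). Components are returned separately
    for logging and ablation.
    """
    if x0_batch.shape != x0_hat_batch.shape or noise.shape != noise_hat.shape:
        raise ValueError("batch shapes must be consistent")
    b = x0_batch.shape[0]
    l_diff = float(np.mean((noise - noise_hat) ** 2))
    l_gapi = 0.0
    l_dtbr = 0.0
    if config.lambda_gapi > 0:
        l_gapi = float(
            np.mean(
                [
                    _gapi.gapi_loss(x0_batch[i], x0_hat_batch[i], params=gapi_params)
                    for i in range(b)
                ]
            )
        )
    if config.lambda_dtbr > 0:
        l_dtbr = float(
            np.mean(
                [
                    _dtbr.dtbr_loss(
                        x0_batch[i], x0_hat_batch[i], class_maps[i], stages[i], dtbr_params
                    )
                    for i in range(b)
                ]
            )
        )
    total = l_diff + config.lambda_gapi * l_gapi + config.lambda_dtbr * l_dtbr
    return total, {"diffusion": l_diff, "gapi": l_gapi, "dtbr": l_dtbr, "total": total}


def _composite_grad_wrt_noise_hat(
    x0, x0_hat_raw, class_maps, stages, noise, noise_hat, t_arr, schedule, config,
    gapi_params, dtbr_params,
):
    """Analytic dL_total / d eps_hat, chaining the bio losses through the
    [0,1]-clamped predicted clean image (zero gradient where clamped)."""
    b = x0.shape[0]
    g = 2.0 * (noise_hat - noise) / noise.size
    if config.lambda_gapi > 0 or config.lambda_dtbr > 0:
        x0_hat = np.clip(x0_hat_raw, 0.0, 1.0)
        inside = (x0_hat_raw > 0.0) & (x0_hat_raw < 1.0)
        for i in range(b):
            ab = schedule.alpha_bar(int(t_arr[i]))
            dx0_deps = -np.sqrt(1.0 - ab) / np.sqrt(ab)
            gx = np.zeros_like(x0[i])
            if config.lambda_gapi > 0:
                gx += config.lambda_gapi * _gapi.gapi_loss_grad(
                    x0[i], x0_hat[i], gapi_params
                )
            if config.lambda_dtbr > 0:
                gx += config.lambda_dtbr * _dtbr.dtbr_loss_grad(
                    x0[i], x0_hat[i], class_maps[i], stages[i], dtbr_params
                )
            g[i] += (gx * inside[i] / b) * dx0_deps
    return g


@dataclass
class Checkpoint:
    """Trained noise predictor with its EMA shadow, config, and training log."""

    params: List[np.ndarray]
    ema_params: List[np.ndarray]
    config: DiffusionConfig
    log: List[Dict[str, float]] = field(default_factory=list)

    def predictor(self, use_ema: bool = True) -> NoisePredictor:
        net = NoisePredictor(channels=self.config.channels, seed=self.config.seed)
        net.set_params(self.ema_params if use_ema else self.params)
        return net

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        arrays.update({f"e{i}": p for i, p in enumerate(self.ema_params)})
        np.savez_compressed(path.with_suffix(".npz"), n=len(self.params), **arrays)
        cfg = asdict(self.config)
        cfg["latent_shape"] = list(cfg["latent_shape"])
        path.with_suffix(".json").write_text(
            json.dumps({"config": cfg, "log": self.log}, indent=2)
        )

    @classmethod
    def load(cls, path) -> "Checkpoint":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as arc:
            n = int(arc["n"])
            params = [arc[f"p{i}"] for i in range(n)]
            ema = [arc[f"e{i}"] for i in range(n)]
        meta = json.loads(path.with_suffix(".json").read_text())
        meta["config"]["latent_shape"] = tuple(meta["config"]["latent_shape"])
        return cls(
            params=params,
            ema_params=ema,
            config=DiffusionConfig(**meta["config"]),
            log=meta["log"],
        )


def train(
    phantoms: Sequence[Phantom],
    config: DiffusionConfig,
    gapi_params: _gapi.GapiParams = _gapi.GapiParams(),
    dtbr_params: _dtbr.DtbrParams = _dtbr.DtbrParams(),
    steps: int = 200,
) -> Checkpoint:
    """Train the epsilon-predictor on phantom images in pixel space.

    ``steps`` counts optimizer steps; each consumes ``grad_accum`` microbatches
    of ``batch_size`` images. All randomness (batching, timesteps, noise,
    dropout, init) flows from ``config.seed``. The log records the composite
    loss components per optimizer step.
    """
    if len(phantoms) == 0:
        raise ValueError("training requires a non-empty dataset")
    if len(phantoms) < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} images, got {len(phantoms)}"
        )
    images = np.stack([p.pixels for p in phantoms])
    class_maps = np.stack([p.class_map for p in phantoms])
    stages = np.array([p.stage for p in phantoms])

    schedule = cosine_schedule(config.T_steps)
    net = NoisePredictor(channels=config.channels, seed=config.seed)
    params = net.get_params()
    opt = AdamW(
        params,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
        warmup_steps=config.warmup_steps,
    )
    ema = EMA(params, decay=config.ema_decay)
    rng = np.random.default_rng(config.seed)
    drop_rng = np.random.default_rng(rng.integers(2**31))

    log: List[Dict[str, float]] = []
    for step in range(1, steps + 1):
        grads_acc = [np.zeros_like(p) for p in params]
        comp_acc = {"diffusion": 0.0, "gapi": 0.0, "dtbr": 0.0, "total": 0.0}
        for _ in range(config.grad_accum):
            idx = rng.choice(len(images), size=config.batch_size, replace=False)
            x0 = images[idx]
            cms = class_maps[idx]
            sts = stages[idx]
            t_arr = rng.integers(1, config.T_steps + 1, size=config.batch_size)
            eps = rng.standard_normal(x0.shape)
            ab = np.array([schedule.alpha_bar(int(t)) for t in t_arr])
            zt = (
                np.sqrt(ab)[:, None, None] * x0
                + np.sqrt(1.0 - ab)[:, None, None] * eps
            )
            eps_hat, cache = net.forward(
                zt, t_arr / config.T_steps, dropout=config.dropout, rng=drop_rng
            )
            x0_hat_raw = (
                zt - np.sqrt(1.0 - ab)[:, None, None] * eps_hat
            ) / np.sqrt(ab)[:, None, None]
            # bio losses see the dynamic-range-clamped prediction: without the
            # clamp, 1/sqrt(alpha_bar_t) blows the image-space losses up at
            # deep timesteps and swamps the epsilon objective
            _, comps = composite_loss(
                x0, np.clip(x0_hat_raw, 0.0, 1.0), None, cms, sts, eps, eps_hat,
                config, gapi_params, dtbr_params,
            )
            g_out = _composite_grad_wrt_noise_hat(
                x0, x0_hat_raw, cms, sts, eps, eps_hat, t_arr, schedule,
                config, gapi_params, dtbr_params,
            )
            grads = net.backward(g_out, cache)
            for ga, g in zip(grads_acc, grads):
                ga += g / config.grad_accum
            for k in comp_acc:
                comp_acc[k] += comps[k] / config.grad_accum
        opt.step(grads_acc)
        ema.update(params)
        log.append({"step": step, **comp_acc})
    return Checkpoint(
        params=[p.copy() for p in params],
        ema_params=[p.copy() for p in ema.shadow],
        config=config,
        log=log,
    )


def inpaint_sample(
    checkpoint: Checkpoint,
    corrupted: np.ndarray,
    mask: np.ndarray,
    class_map: Optional[np.ndarray] = None,
    stage: Optional[int] = None,
    steps: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Mask-conditioned reverse sampling (pixel space).

    At every reverse step the known (unmasked) region is re-imposed by
    forward-diffusing the observed pixels to the current timestep and
    overwriting; the masked region is generated by the learned denoiser. The
    reverse kernel variance is the schedule's posterior variance (not
    learned). Deterministic given ``seed``.
    """
    config = checkpoint.config
    schedule = cosine_schedule(config.T_steps)
    net = checkpoint.predictor(use_ema=True)
    mask = np.asarray(mask, bool)
    known = ~mask
    rng = np.random.default_rng(seed)
    x_obs = np.asarray(corrupted, dtype=np.float64)

    timesteps = list(range(config.T_steps, 0, -1))
    if steps is not None and steps < config.T_steps:
        sel = np.unique(np.linspace(1, config.T_steps, steps).round().astype(int))
        timesteps = sorted(sel.tolist(), reverse=True)

    z = rng.standard_normal(corrupted.shape)
    for i, t in enumerate(timesteps):
        t_prev = timesteps[i + 1] if i + 1 < len(timesteps) else 0
        ab_t = schedule.alpha_bar(t)
        ab_prev = schedule.alpha_bar(t_prev)
        eps_hat, _ = net.forward(z[None], np.array([t / config.T_steps]))
        eps_hat = eps_hat[0]
        x0_hat = np.clip((z - np.sqrt(1 - ab_t) * eps_hat) / np.sqrt(ab_t), 0.0, 1.0)
        # DDPM posterior q(z_{t_prev} | z_t, x0_hat)
        beta_eff = 1.0 - ab_t / ab_prev
        var = beta_eff * (1.0 - ab_prev) / (1.0 - ab_t)
        mean = (
            np.sqrt(ab_prev) * beta_eff / (1.0 - ab_t) * x0_hat
            + np.sqrt(ab_t / ab_prev) * (1.0 - ab_prev) / (1.0 - ab_t) * z
        )
        noise = rng.standard_normal(z.shape) if t_prev > 0 else 0.0
        z = mean + np.sqrt(max(var, 0.0)) * noise
        # re-impose the known region at the new noise level
        if t_prev > 0:
            z_known = forward_diffuse(x_obs, t_prev, schedule, rng.standard_normal(z.shape))
        else:
            z_known = x_obs
        z = np.where(known, z_known, z)
    return np.clip(z, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Toy autoencoder
# ---------------------------------------------------------------------------

@dataclass
class AeConfig:
    mode: str = "pca"  # "pca" | "identity"
    patch: int = 8
    n_components: int = 4
    refine: bool = True  # learned deblocking filter on the decoder output


class ToyAutoencoder:
    """Patchwise linear autoencoder to a 4-channel latent at 1/8 resolution.

    Non-overlapping 8x8 patches are projected onto the top principal
    components of the training patches (the closed-form minimizer of the
    mean-squared reconstruction error for a linear code), giving a latent of
    shape (4, H/8, W/8) — the same 8x compression ratio as a paper-scale
    512 -> 64 VAE. The decoder optionally applies a phase-aware 5x5 linear
    deblocking filter — one ridge fit per within-block pixel position, since
    blocking artifacts depend on a pixel's phase inside its 8x8 block —
    mapping decoded neighborhoods to the original pixels (both stages are
    closed-form mean-squared-error fits). ``identity`` mode bypasses the
    autoencoder entirely.
    """

    def __init__(self, config: AeConfig = AeConfig()):
        self.config = config
        self.mean_: Optional[np.ndarray] = None
        self.components_: Optional[np.ndarray] = None
        self.refine_weights_: Optional[np.ndarray] = None

    def _check(self, images: np.ndarray):
        if images.ndim != 3:
            raise ValueError("images must be (B, H, W)")
        _, h, w = images.shape
        p = self.config.patch
        if h % p or w % p:
            raise ValueError(f"image sides must be divisible by {p}, got {h}x{w}")

    def _patches(self, images: np.ndarray) -> np.ndarray:
        b, h, w = images.shape
        p = self.config.patch
        x = images.reshape(b, h // p, p, w // p, p).transpose(0, 1, 3, 2, 4)
        return x.reshape(-1, p * p)

    def fit(self, images: np.ndarray) -> "ToyAutoencoder":
        if self.config.mode == "identity":
            return self
        self._check(images)
        x = self._patches(images)
        self.mean_ = x.mean(axis=0)
        xc = x - self.mean_
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        self.components_ = vt[: self.config.n_components]
        if self.config.refine:
            coarse = self._linear_decode(self.encode(images))
            self.refine_weights_ = self._fit_refine(coarse, images)
        return self

    @staticmethod
    def _neighborhoods(images: np.ndarray, k: int = 5) -> np.ndarray:
        """(B, H, W, k*k) tensor of the k x k neighborhood of every pixel."""
        b, h, w = images.shape
        r = k // 2
        xp = np.pad(images, ((0, 0), (r, r), (r, r)), mode="edge")
        cols = [
            xp[:, dr : dr + h, dc : dc + w] for dr in range(k) for dc in range(k)
        ]
        return np.stack(cols, axis=-1)

    def _fit_refine(self, coarse: np.ndarray, target: np.ndarray) -> np.ndarray:
        p = self.config.patch
        nb = self._neighborhoods(coarse)
        f = nb.shape[-1]
        weights = np.empty((p, p, f + 1))
        ridge = 1e-6 * np.eye(f + 1)
        for pr in range(p):
            for pc in range(p):
                a = nb[:, pr::p, pc::p, :].reshape(-1, f)
                a = np.concatenate([a, np.ones((a.shape[0], 1))], axis=1)
                y = target[:, pr::p, pc::p].reshape(-1)
                weights[pr, pc] = np.linalg.solve(a.T @ a + ridge, a.T @ y)
        return weights

    def _apply_refine(self, coarse: np.ndarray) -> np.ndarray:
        p = self.config.patch
        nb = self._neighborhoods(coarse)
        b, h, w, f = nb.shape
        out = np.empty_like(coarse)
        for pr in range(p):
            for pc in range(p):
                wgt = self.refine_weights_[pr, pc]
                a = nb[:, pr::p, pc::p, :]
                out[:, pr::p, pc::p] = a @ wgt[:-1] + wgt[-1]
        return out

    def encode(self, images: np.ndarray) -> np.ndarray:
        if self.config.mode == "identity":
            return images[:, None]
        self._check(images)
        if self.components_ is None:
            raise RuntimeError("autoencoder not fitted")
        b, h, w = images.shape
        p, k = self.config.patch, self.config.n_components
        z = (self._patches(images) - self.mean_) @ self.components_.T
        return z.reshape(b, h // p, w // p, k).transpose(0, 3, 1, 2)

    def _linear_decode(self, latents: np.ndarray) -> np.ndarray:
        b, k, hh, ww = latents.shape
        p = self.config.patch
        z = latents.transpose(0, 2, 3, 1).reshape(-1, k)
        x = z @ self.components_ + self.mean_
        x = x.reshape(b, hh, ww, p, p).transpose(0, 1, 3, 2, 4)
        return x.reshape(b, hh * p, ww * p)

    def decode(self, latents: np.ndarray) -> np.ndarray:
        if self.config.mode == "identity":
            return latents[:, 0]
        x = self._linear_decode(latents)
        if self.refine_weights_ is not None:
            x = self._apply_refine(x)
        return np.clip(x, 0.0, 1.0)


def toy_autoencoder_roundtrip(
    images: np.ndarray, ae_config: AeConfig = AeConfig()
) -> Tuple[np.ndarray, np.ndarray]:
    """Fit the toy autoencoder on ``images`` and return (latents, recons)."""
    ae = ToyAutoencoder(ae_config).fit(images)
    latents = ae.encode(images)
    return latents, ae.decode(latents)
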