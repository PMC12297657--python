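"""Deciduous Transition-Based Reconstruction (DTBR).

DTBR imputes missing pixels from a stage-aware transition probability model:
a conditional histogram over quantized pixel values, indexed by developmental
stage (1..6), region class (background/gum/tooth), and a quantized
neighborhood-context bin (the mean intensity of the pixel's 8 neighbors).
The model is built from labeled exemplar phantoms — the in-package stand-in
for an expert-annotated developmental pattern library — and a masked pixel is
filled with the conditional expectation sum_k p_k * v_k over value-bin
centers v_k.

The DTBR loss enforces stage consistency: region-weighted squared error plus
a temporal term comparing per-region transition features (mean intensity,
Sobel edge density, foreground fraction) between the original and the
reconstruction.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import correlate, label
from scipy.signal import convolve2d

from . import phantom as _ph
from ._peel import onion_peel
from .gapi import SOBEL_DC, SOBEL_DR, gradient_field, _known_neighbor_mean

NUM_STAGES = 6
NUM_REGIONS = 3

_CONTEXT_KERNEL = np.ones((3, 3)) / 8.0
_CONTEXT_KERNEL[1, 1] = 0.0


def _default_region_weights() -> np.ndarray:
    """D(r, S): 1 everywhere except tooth rows at mixed-dentition stages 3-4,
    where transition emphasis is highest (weight 2)."""
    w = np.ones((NUM_STAGES, NUM_REGIONS))
    w[2, _ph.TOOTH] = 2.0
    w[3, _ph.TOOTH] = 2.0
    return w


@dataclass(frozen=True)
class DtbrParams:
    """Weights of the DTBR loss and model resolution.

    ``region_weights[stage-1, region]`` is the developmental weighting D(r,S);
    ``lambda_temporal`` balances the transition-feature term; K and B are the
    value and context bin counts of the transition model.
    """

    lambda_temporal: float = 0.5
    region_weights: np.ndarray = field(default_factory=_default_region_weights)
    K: int = 16
    B: int = 8

    def __post_init__(self):
        rw = np.asarray(self.region_weights, dtype=float)
        if rw.shape != (NUM_STAGES, NUM_REGIONS):
            raise ValueError(f"region_weights must be 6x3, got {rw.shape}")
        if (rw <= 0).any():
            raise ValueError("region_weights must be strictly positive")
        if self.lambda_temporal < 0:
            raise ValueError("lambda_temporal must be >= 0")
        object.__setattr__(self, "region_weights", rw)


@dataclass(frozen=True)
class TransitionModel:
    """Stage/region/context-conditioned distribution over quantized values."""

    probs: np.ndarray          # (6, 3, B, K)
    bin_edges: np.ndarray      # K + 1 increasing edges spanning [0, 1]
    context_edges: np.ndarray  # B + 1 increasing edges spanning [0, 1]
    smoothing: float

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 4 or p.shape[:2] != (NUM_STAGES, NUM_REGIONS):
            raise ValueError(f"probs must be (6, 3, B, K), got {p.shape}")
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        sums = p.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("every conditional distribution must sum to 1")

    @property
    def K(self) -> int:
        return self.probs.shape[-1]

    @property
    def B(self) -> int:
        return self.probs.shape[-2]

    @property
    def bin_centers(self) -> np.ndarray:
        e = np.asarray(self.bin_edges)
        return (e[:-1] + e[1:]) / 2.0

    def save(self, path) -> None:
        """Write a compressed archive plus a JSON sidecar."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            probs=self.probs,
            bin_edges=self.bin_edges,
            context_edges=self.context_edges,
        )
        digest = hashlib.sha256(np.ascontiguousarray(self.probs).tobytes()).hexdigest()
        sidecar = {
            "smoothing": self.smoothing,
            "K": int(self.K),
            "B": int(self.B),
            "probs_sha256": digest,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "TransitionModel":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as arc:
            probs = arc["probs"]
            bin_edges = arc["bin_edges"]
            context_edges = arc["context_edges"]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            probs=probs,
            bin_edges=bin_edges,
            context_edges=context_edges,
            smoothing=float(sidecar["smoothing"]),
        )


def _bin_index(values, edges):
    """Left-closed bin index into len(edges)-1 bins, clipped to the span."""
    idx = np.digitize(values, edges) - 1
    return np.clip(idx, 0, len(edges) - 2)


def neighborhood_context(pixels: np.ndarray) -> np.ndarray:
    """Mean of the 8 neighbors of each pixel (reflect-padded borders)."""
    return correlate(pixels.astype(np.float64), _CONTEXT_KERNEL, mode="reflect")


def build_transition_model(
    exemplars: Sequence[_ph.Phantom],
    K: int = 16,
    B: int = 8,
    smoothing: float = 1.0,
) -> TransitionModel:
    """Tally (stage, region, context bin, value bin) counts over exemplars.

    Probabilities are Laplace-smoothed: (count + smoothing) / (row total +
    K * smoothing). With smoothing > 0, stages absent from the exemplars get
    uniform rows (with a warning); with smoothing = 0 they are an error.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if B < 1:
        raise ValueError("B must be >= 1")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    bin_edges = np.linspace(0.0, 1.0, K + 1)
    context_edges = np.linspace(0.0, 1.0, B + 1)
    counts = np.zeros((NUM_STAGES, NUM_REGIONS, B, K))
    seen = set()
    for ex in exemplars:
        seen.add(ex.stage)
        ctx = _bin_index(neighborhood_context(ex.pixels), context_edges)
        val = _bin_index(ex.pixels, bin_edges)
        s = ex.stage - 1
        flat = (
            ex.class_map.astype(np.int64).ravel() * (B * K)
            + ctx.ravel() * K
            + val.ravel()
        )
        counts[s] += np.bincount(flat, minlength=NUM_REGIONS * B * K).reshape(
            NUM_REGIONS, B, K
        )
    missing = sorted(set(range(1, NUM_STAGES + 1)) - seen)
    if missing and smoothing == 0:
        raise ValueError(
            f"stages {missing} absent from exemplars and smoothing is 0; "
            "their conditionals would be undefined"
        )
    if missing:
        warnings.warn(
            f"stages {missing} absent from exemplars; their rows fall back "
            "to uniform via smoothing",
            stacklevel=2,
        )
    totals = counts.sum(axis=-1, keepdims=True)
    if smoothing == 0 and (totals == 0).any():
        # rows for (stage, region, context) cells never observed: uniform
        probs = np.where(
            totals > 0, counts / np.where(totals > 0, totals, 1.0), 1.0 / K
        )
    else:
        probs = (counts + smoothing) / (totals + K * smoothing)
    return TransitionModel(
        probs=probs,
        bin_edges=bin_edges,
        context_edges=context_edges,
        smoothing=smoothing,
    )


def dtbr_expected_value(
    model: TransitionModel, stage: int, region: int, context_value: float
) -> float:
    """Conditional expectation sum_k p_k * v_k of the value-bin centers."""
    if not (0.0 <= context_value <= 1.0):
        raise ValueError("context_value must lie in [0, 1]")
    b = int(_bin_index(np.asarray(context_value), model.context_edges))
    p = model.probs[stage - 1, region, b]
    return float(p @ model.bin_centers)


def dtbr_impute(
    pixels: np.ndarray,
    mask: np.ndarray,
    class_map: np.ndarray,
    stage: int,
    model: TransitionModel,
) -> np.ndarray:
    """Fill masked pixels with the stage-conditioned expected value.

    Shares the onion-peel schedule with GAPI; a pixel's context is the mean
    of its known 8-neighbors at the time its peel runs.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return pixels.copy()

    def fill_peel(snapshot, known, coords):
        values = []
        for p in coords:
            ctx = _known_neighbor_mean(snapshot, known, p)
            values.append(
                dtbr_expected_value(model, stage, int(class_map[p]), float(np.clip(ctx, 0, 1)))
            )
        return values

    out, _ = onion_peel(pixels, mask, fill_peel)
    return out


# ---------------------------------------------------------------------------
# Stage classification
# ---------------------------------------------------------------------------

_LABEL_4CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _stage_features(class_map: np.ndarray) -> np.ndarray:
    """(tooth component count, tooth area fraction, arch gap fraction)."""
    tooth = class_map == _ph.TOOTH
    _, n_teeth = label(tooth, structure=_LABEL_4CONN)
    area_frac = float(tooth.mean())
    arch_cols = ((class_map == _ph.GUM) | tooth).any(axis=0)
    if arch_cols.any():
        gap_frac = float((~tooth.any(axis=0))[arch_cols].mean())
    else:
        gap_frac = 1.0
    return np.array([float(n_teeth), area_frac, gap_frac])


@dataclass(frozen=True)
class StageCentroids:
    """Per-stage feature centroids with the scale used to whiten distances."""

    centroids: np.ndarray  # (6, 3)
    scale: np.ndarray      # (3,)


def build_stage_centroids(
    size: Tuple[int, int] = (64, 64),
    seeds_per_stage: int = 10,
    noise_sd: float = 0.0,
    base_seed: int = 0,
) -> StageCentroids:
    """Average the stage features of seeded phantoms into reference centroids."""
    feats = np.zeros((NUM_STAGES, 3))
    all_feats = []
    for s in range(1, NUM_STAGES + 1):
        rows = [
            _stage_features(
                _ph.generate_phantom(s, size, seed=base_seed + 1000 * s + i, noise_sd=noise_sd).class_map
            )
            for i in range(seeds_per_stage)
        ]
        feats[s - 1] = np.mean(rows, axis=0)
        all_feats.extend(rows)
    scale = np.std(np.asarray(all_feats), axis=0)
    scale[scale == 0] = 1.0
    return StageCentroids(centroids=feats, scale=scale)


def classify_stage(
    image: np.ndarray,
    class_map: np.ndarray,
    age_months: Optional[int] = None,
    reference: Optional[StageCentroids] = None,
) -> int:
    """Developmental stage of a dentition image.

    Patient metadata takes precedence: with ``age_months`` the stage is the
    age bracket. Otherwise the image's morphology features are matched to the
    nearest reference centroid (ties to the lower stage).
    """
    if age_months is not None:
        return _ph.age_to_stage(age_months)
    if reference is None:
        raise ValueError("need either age_months or reference centroids")
    if image.shape != class_map.shape:
        raise ValueError("image and class_map must be aligned")
    f = _stage_features(class_map) / reference.scale
    d = np.linalg.norm(reference.centroids / reference.scale - f, axis=1)
    return int(np.argmin(d)) + 1  # argmin takes the first == lowest stage on ties


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def transition_features(
    region_pixels: np.ndarray,
    stage: int | None = None,
    region_mask: Optional[np.ndarray] = None,
    tooth_threshold: float = _ph.DEFAULT_THRESHOLDS[1],
) -> np.ndarray:
    """Per-region transition features: (mean intensity, Sobel edge density,
    foreground fraction above the tooth threshold).

    ``region_pixels`` is a 2D intensity array; ``region_mask`` restricts the
    statistics to a subset of it (gradients are still evaluated on the full
    array). The features are stage-independent summaries; ``stage`` is
    accepted for interface symmetry with the loss.
    """
    px = np.asarray(region_pixels, dtype=np.float64)
    if region_mask is None:
        region_mask = np.ones(px.shape, dtype=bool)
    if px.ndim != 2 or not region_mask.any():
        raise ValueError("region must be a non-empty 2D pixel array")
    _, _, mag = gradient_field(px)
    sel = region_mask
    return np.array(
        [
            float(px[sel].mean()),
            float(mag[sel].mean()),
            float((px[sel] >= tooth_threshold).mean()),
        ]
    )


def dtbr_loss(
    original: np.ndarray,
    reconstructed: np.ndarray,
    class_map: np.ndarray,
    stage: int,
    params: DtbrParams = DtbrParams(),
) -> float:
    """Stage-consistency loss: sum_r D(r,S) * MSE(I_r, Î_r) +
    lambda_temporal * sum_r ||T(I_r) - T(Î_r)||^2. Empty regions contribute 0."""
    if original.shape != reconstructed.shape:
        raise ValueError("original and reconstructed shapes must match")
    o = original.astype(np.float64)
    r = reconstructed.astype(np.float64)
    total = 0.0
    for region in range(NUM_REGIONS):
        sel = class_map == region
        if not sel.any():
            continue
        d_rs = params.region_weights[stage - 1, region]
        total += d_rs * float(np.mean((o[sel] - r[sel]) ** 2))
        if params.lambda_temporal > 0:
            t_o = transition_features(o, stage, sel)
            t_r = transition_features(r, stage, sel)
            total += params.lambda_temporal * float(np.sum((t_o - t_r) ** 2))
    return total


def _sobel_reflect_adjoint(upstream: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Adjoint of reflect-padded 3x3 correlation (ndimage 'reflect' ==
    symmetric padding): full convolution then fold the pad rows/cols back."""
    h, w = upstream.shape
    g = convolve2d(upstream, kernel, mode="full")  # (h+2, w+2)
    out = g[1 : h + 1, 1 : w + 1].copy()
    out[0, :] += g[0, 1 : w + 1]
    out[-1, :] += g[h + 1, 1 : w + 1]
    out[:, 0] += g[1 : h + 1, 0]
    out[:, -1] += g[1 : h + 1, w + 1]
    out[0, 0] += g[0, 0]
    out[0, -1] += g[0, w + 1]
    out[-1, 0] += g[h + 1, 0]
    out[-1, -1] += g[h + 1, w + 1]
    return out


def dtbr_loss_grad(
    original: np.ndarray,
    reconstructed: np.ndarray,
    class_map: np.ndarray,
    stage: int,
    params: DtbrParams = DtbrParams(),
) -> np.ndarray:
    """Analytic d dtbr_loss / d reconstructed.

    The foreground-fraction feature is piecewise constant, so its gradient is
    zero almost everywhere and omitted; mean-intensity and edge-density
    feature gradients are exact (the edge term chains through the Sobel
    stencils via their reflect-padding adjoint).
    """
    o = original.astype(np.float64)
    r = reconstructed.astype(np.float64)
    grad = np.zeros_like(r)
    gr_r, gc_r, mag_r = gradient_field(r)
    safe = np.where(mag_r > 0, mag_r, 1.0)
    for region in range(NUM_REGIONS):
        sel = class_map == region
        n = int(sel.sum())
        if n == 0:
            continue
        d_rs = params.region_weights[stage - 1, region]
        grad[sel] += d_rs * 2.0 * (r[sel] - o[sel]) / n
        if params.lambda_temporal > 0:
            t_o = transition_features(o, stage, sel)
            t_r = transition_features(r, stage, sel)
            delta = t_r - t_o
            # mean intensity
            grad[sel] += params.lambda_temporal * 2.0 * delta[0] / n
            # edge density: d mean|grad| / d r
            up = np.where(sel, 1.0 / n, 0.0)
            gx = _sobel_reflect_adjoint(up * np.where(mag_r > 0, gr_r / safe, 0.0), SOBEL_DR)
            gy = _sobel_reflect_adjoint(up * np.where(mag_r > 0, gc_r / safe, 0.0), SOBEL_DC)
            grad += params.lambda_temporal * 2.0 * delta[1] * (gx + gy)
    return grad
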