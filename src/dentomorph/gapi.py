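"""Gum-Adaptive Pixel Imputation (GAPI).

GAPI fills missing pixels from their 8-connected neighborhood with weights
that mimic how gum tissue adapts to adjacent structures. Each known neighbor
p_i of a masked target pixel receives a raw weight

    W(p_i) = alpha * S(p_i) + beta * C(p_i, target) + gamma * T(p_i)

where S is structural significance (gradient magnitude times the cosine of
the angle between the local gradient and the direction toward the target,
clamped at zero so edges pointing away from the hole attract no weight), C is
a continuity factor (Gaussian affinity of the neighbor's intensity to the
mean of the target's known neighbors, scaled by 1 for axial and 1/sqrt(2) for
diagonal neighbors), and T is a tissue-compatibility score (1 when the
neighbor's class matches the modal class around the target, ``tau``
otherwise). Weights are normalized to sum to one and the imputed value is the
weighted mean of the known neighbor intensities. Holes are filled by the
shared onion-peel schedule, recomputing gradients each peel.

The GAPI loss scores a reconstruction by salience-weighted squared error plus
a structural term penalizing changes in 8-neighbor intensity differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.ndimage import correlate

from ._peel import NEIGHBOR_OFFSETS, onion_peel

# Sobel stencils; rows are the first image axis. Reflective border padding.
SOBEL_DC = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_DR = SOBEL_DC.T

# Unordered 8-adjacent pixel pairs are enumerated once via these offsets.
_PAIR_OFFSETS = [(0, 1), (1, 0), (1, 1), (1, -1)]


@dataclass(frozen=True)
class GapiParams:
    """Tunable weights of the GAPI neighborhood model.

    alpha/beta/gamma balance structural significance, continuity, and tissue
    compatibility (defaults 0.5/0.3/0.2, decreasing emphasis); sigma_c is the
    continuity bandwidth in intensity units; tau the off-class compatibility
    score; lambda_structure weights the structural term of the loss.
    """

    alpha: float = 0.5
    beta: float = 0.3
    gamma: float = 0.2
    sigma_c: float = 0.1
    tau: float = 0.25
    lambda_structure: float = 0.5

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.lambda_structure) < 0:
            raise ValueError("alpha, beta, gamma, lambda_structure must be >= 0")
        if self.alpha + self.beta + self.gamma <= 0:
            raise ValueError("alpha + beta + gamma must be positive")
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if not (0 < self.tau <= 1):
            raise ValueError("tau must lie in (0, 1]")


@dataclass(frozen=True)
class NeighborhoodWeights:
    """Normalized weights over the known 8-neighbors of a target pixel."""

    target: Tuple[int, int]
    entries: List[Tuple[Tuple[int, int], float]]

    def __post_init__(self):
        if len(self.entries) > 8:
            raise ValueError("at most 8 neighbors exist")
        if self.entries:
            total = sum(w for _, w in self.entries)
            if any(w < 0 for _, w in self.entries):
                raise ValueError("weights must be non-negative")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"weights must sum to 1, got {total}")


def gradient_field(pixels: np.ndarray):
    """Per-pixel Sobel gradient (d/drow, d/dcol) and magnitude, reflect-padded."""
    if pixels.ndim != 2 or min(pixels.shape) < 3:
        raise ValueError(f"image must be at least 3x3, got shape {pixels.shape}")
    img = pixels.astype(np.float64)
    gc = correlate(img, SOBEL_DC, mode="reflect")
    gr = correlate(img, SOBEL_DR, mode="reflect")
    return gr, gc, np.hypot(gr, gc)


def structural_significance(
    grad: Tuple[float, float],
    p_i: Tuple[int, int],
    p_target: Tuple[int, int],
) -> float:
    """S(p_i) = ||grad|| * max(0, cos(grad, direction p_i -> target))."""
    if p_i == p_target:
        raise ValueError("p_i must differ from p_target")
    gr, gc = float(grad[0]), float(grad[1])
    mag = math.hypot(gr, gc)
    if mag == 0.0:
        return 0.0
    dr, dc = p_target[0] - p_i[0], p_target[1] - p_i[1]
    dist = math.hypot(dr, dc)
    cos = (gr * dr + gc * dc) / (mag * dist)
    return mag * max(0.0, cos)


def _known_neighbor_mean(pixels, known, p_target) -> float:
    h, w = pixels.shape
    vals = [
        pixels[p_target[0] + dr, p_target[1] + dc]
        for dr, dc in NEIGHBOR_OFFSETS
        if 0 <= p_target[0] + dr < h
        and 0 <= p_target[1] + dc < w
        and known[p_target[0] + dr, p_target[1] + dc]
    ]
    if not vals:
        raise ValueError(f"target {p_target} has no known 8-neighbor")
    return float(np.mean(vals))


def continuity_factor(
    pixels: np.ndarray,
    mask: np.ndarray,
    p_i: Tuple[int, int],
    p_target: Tuple[int, int],
    sigma_c: float = 0.1,
) -> float:
    """Gaussian intensity affinity to the known-neighbor mean, distance-scaled."""
    if mask[p_i]:
        raise ValueError(f"p_i {p_i} is masked; continuity needs a known pixel")
    m_n = _known_neighbor_mean(pixels, ~np.asarray(mask, bool), p_target)
    d_i = float(pixels[p_i]) - m_n
    gauss = math.exp(-(d_i * d_i) / (2.0 * sigma_c * sigma_c))
    diagonal = p_i[0] != p_target[0] and p_i[1] != p_target[1]
    return gauss * (1.0 / math.sqrt(2.0) if diagonal else 1.0)


def tissue_compatibility(
    class_map: np.ndarray,
    mask: np.ndarray,
    p_i: Tuple[int, int],
    p_target: Tuple[int, int],
    tau: float = 0.25,
) -> float:
    """1 if p_i shares the modal class of the target's known neighbors, else tau.

    Modal ties resolve by priority tooth > gum > background, which coincides
    with the numeric class order 2 > 1 > 0.
    """
    h, w = class_map.shape
    known = ~np.asarray(mask, bool)
    classes = [
        int(class_map[p_target[0] + dr, p_target[1] + dc])
        for dr, dc in NEIGHBOR_OFFSETS
        if 0 <= p_target[0] + dr < h
        and 0 <= p_target[1] + dc < w
        and known[p_target[0] + dr, p_target[1] + dc]
    ]
    if not classes:
        raise ValueError(f"target {p_target} has no known 8-neighbor")
    counts = np.bincount(classes, minlength=3)
    modal = int(np.flatnonzero(counts == counts.max()).max())
    return 1.0 if int(class_map[p_i]) == modal else float(tau)


def _weights_at(
    img: np.ndarray,
    known: np.ndarray,
    class_map: np.ndarray,
    grads: Tuple[np.ndarray, np.ndarray],
    p_target: Tuple[int, int],
    params: GapiParams,
) -> NeighborhoodWeights:
    """Raw GAPI weights from precomputed gradients, normalized."""
    h, w = img.shape
    gr, gc = grads
    mask = ~known
    neighbors = [
        (p_target[0] + dr, p_target[1] + dc)
        for dr, dc in NEIGHBOR_OFFSETS
        if 0 <= p_target[0] + dr < h
        and 0 <= p_target[1] + dc < w
        and known[p_target[0] + dr, p_target[1] + dc]
    ]
    if not neighbors:
        raise ValueError(f"isolated target {p_target}: no known 8-neighbor")
    raw = []
    for p_i in neighbors:
        s = structural_significance((gr[p_i], gc[p_i]), p_i, p_target)
        c = continuity_factor(img, mask, p_i, p_target, params.sigma_c)
        t = tissue_compatibility(class_map, mask, p_i, p_target, params.tau)
        raw.append(params.alpha * s + params.beta * c + params.gamma * t)
    total = float(sum(raw))
    if total <= 0.0:  # flat region with gamma=0: fall back to uniform
        weights = [1.0 / len(neighbors)] * len(neighbors)
    else:
        weights = [r / total for r in raw]
    return NeighborhoodWeights(target=p_target, entries=list(zip(neighbors, weights)))


def neighbor_weights(
    pixels: np.ndarray,
    mask: np.ndarray,
    class_map: np.ndarray,
    p_target: Tuple[int, int],
    params: GapiParams = GapiParams(),
) -> NeighborhoodWeights:
    """Normalized GAPI weights over the known 8-neighbors of a masked target.

    Gradients are computed on the sentinel-filled image (masked pixels read
    as 0), matching the state the imputer sees.
    """
    mask = np.asarray(mask, bool)
    if not mask[p_target]:
        raise ValueError(f"target {p_target} is not masked")
    img = np.where(mask, 0.0, pixels.astype(np.float64))
    gr, gc, _ = gradient_field(img)
    return _weights_at(img, ~mask, class_map, (gr, gc), p_target, params)


def gapi_impute(
    pixels: np.ndarray,
    mask: np.ndarray,
    class_map: np.ndarray,
    params: GapiParams = GapiParams(),
) -> np.ndarray:
    """Fill every masked pixel by GAPI-weighted averaging, onion-peel ordered.

    Gradients are recomputed each peel so continuity with freshly imputed
    pixels informs later peels. Unmasked pixels are returned untouched.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return pixels.copy()

    def fill_peel(snapshot, known, coords):
        gr, gc, _ = gradient_field(snapshot)
        values = []
        for p in coords:
            nw = _weights_at(snapshot, known, class_map, (gr, gc), p, params)
            values.append(
                sum(wt * snapshot[q] for q, wt in nw.entries)
            )
        return values

    out, _ = onion_peel(pixels, mask, fill_peel)
    return out


def _salience(original: np.ndarray) -> np.ndarray:
    """Per-pixel salience: gradient magnitude max-normalized to [0, 1];
    a flat image degrades to uniform salience (plain MSE). Unlike
    gradient_field this accepts images down to 2x2 (the loss has no 3x3
    stencil precondition)."""
    img = original.astype(np.float64)
    mag = np.hypot(
        correlate(img, SOBEL_DR, mode="reflect"),
        correlate(img, SOBEL_DC, mode="reflect"),
    )
    peak = mag.max()
    if peak == 0:
        return np.ones_like(mag)
    return mag / peak


def gapi_loss(
    original: np.ndarray,
    reconstructed: np.ndarray,
    mask: np.ndarray | None = None,
    class_map: np.ndarray | None = None,
    params: GapiParams = GapiParams(),
) -> float:
    """Structural-continuity loss of a reconstruction.

    mean_p w_p (v_p - v̂_p)^2 + lambda_structure * mean over 8-adjacent pairs
    of w(p,q) (R - R̂)^2, with R(p,q) = I(p) - I(q), w(p,q) = (w_p + w_q)/2
    and w_p the normalized gradient magnitude of the original. Both sums are
    averaged over their counts so the loss is resolution-independent.
    """
    if original.shape != reconstructed.shape:
        raise ValueError("original and reconstructed shapes must match")
    o = original.astype(np.float64)
    r = reconstructed.astype(np.float64)
    w = _salience(o)
    term1 = float(np.mean(w * (o - r) ** 2))
    acc, count = 0.0, 0
    for dr, dc in _PAIR_OFFSETS:
        op, oq, rp, rq, wp, wq = _pair_views(o, r, w, dr, dc)
        d = (op - oq) - (rp - rq)
        acc += float(np.sum(0.5 * (wp + wq) * d * d))
        count += op.size
    term2 = params.lambda_structure * acc / count if count else 0.0
    return term1 + term2


def gapi_loss_grad(
    original: np.ndarray,
    reconstructed: np.ndarray,
    params: GapiParams = GapiParams(),
) -> np.ndarray:
    """Analytic d gapi_loss / d reconstructed (salience fixed by the original)."""
    o = original.astype(np.float64)
    r = reconstructed.astype(np.float64)
    w = _salience(o)
    grad = -2.0 * w * (o - r) / o.size
    count = sum(_pair_views(o, r, w, dr, dc)[0].size for dr, dc in _PAIR_OFFSETS)
    if count:
        scale = 2.0 * params.lambda_structure / count
        for dr, dc in _PAIR_OFFSETS:
            op, oq, rp, rq, wp, wq = _pair_views(o, r, w, dr, dc)
            g = scale * 0.5 * (wp + wq) * ((op - oq) - (rp - rq))
            sl_p, sl_q = _pair_slices(o.shape, dr, dc)
            grad[sl_p] -= g
            grad[sl_q] += g
    return grad


def _pair_slices(shape, dr, dc):
    h, w = shape
    rp = slice(0, h - dr)
    rq = slice(dr, h)
    if dc >= 0:
        cp, cq = slice(0, w - dc), slice(dc, w)
    else:
        cp, cq = slice(-dc, w), slice(0, w + dc)
    return (rp, cp), (rq, cq)


def _pair_views(o, r, w, dr, dc):
    sl_p, sl_q = _pair_slices(o.shape, dr, dc)
    return o[sl_p], o[sl_q], r[sl_p], r[sl_q], w[sl_p], w[sl_q]
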