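"""Synthetic dental phantoms with ground-truth class maps and corruption masks.

The phantom is a deliberately schematic stand-in for clinical dental
photographs/radiographs: an arch of bright elliptical teeth along a parabola,
bordered by a gum band of intermediate intensity over a dark background.
Dentition morphology is parameterized by a developmental stage 1..6 spanning
ages 2-14 years (early primary dentition through the maturation phase of the
permanent dentition): tooth count and size grow with stage, while exfoliation
gaps and partially erupted teeth peak during the mixed-dentition stages.

Every generator is a pure function of its parameters and a seed, so the rest
of the package is testable without any image downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

BACKGROUND, GUM, TOOTH = 0, 1, 2

#: Intensity rendered for each class (before additive noise).
CLASS_INTENSITY = {BACKGROUND: 0.15, GUM: 0.5, TOOTH: 0.9}

#: Default thresholds splitting [0,1] intensities into background/gum/tooth.
DEFAULT_THRESHOLDS = (0.3, 0.7)

#: Stage -> dentition morphology. ``n_teeth`` is the nominal tooth count,
#: ``missing_frac`` the fraction of positions left empty (erupting or
#: exfoliated teeth; the realized count is round(frac * n), so the rendered
#: tooth count is deterministic per stage), ``partial_frac`` the fraction of
#: rendered teeth drawn half-erupted (lower half only), and ``size_rel`` the
#: tooth semi-minor axis relative to min(H, W). Rendered counts are
#: 7, 8, 9, 10, 11, 12 for stages 1..6 — strictly increasing, mirroring the
#: primary -> mixed -> permanent dentition progression.
STAGE_MORPHOLOGY = {
    1: dict(n_teeth=8, size_rel=0.030, missing_frac=0.125, partial_frac=0.25),
    2: dict(n_teeth=9, size_rel=0.032, missing_frac=0.112, partial_frac=0.0),
    3: dict(n_teeth=11, size_rel=0.034, missing_frac=0.182, partial_frac=0.28),
    4: dict(n_teeth=12, size_rel=0.036, missing_frac=0.167, partial_frac=0.20),
    5: dict(n_teeth=12, size_rel=0.040, missing_frac=0.083, partial_frac=0.09),
    6: dict(n_teeth=12, size_rel=0.044, missing_frac=0.0, partial_frac=0.0),
}

#: Age brackets in months for the six developmental stages (left-closed).
STAGE_AGE_BRACKETS = {
    1: (24, 48),   # early primary (2-4 y): initial dentition
    2: (48, 72),   # late primary (4-6 y): complete primary dentition
    3: (72, 96),   # early mixed (6-8 y): first molars erupting
    4: (96, 120),  # late mixed (8-10 y): transition peak
    5: (120, 144), # early permanent (10-12 y)
    6: (144, 168), # extended range (12-14 y): maturation phase
}

AGE_MIN, AGE_MAX = 24, 168

CORRUPTION_KINDS = ("rectangles", "blobs", "bernoulli")


@dataclass(frozen=True)
class Phantom:
    """A synthetic dental image with its noise-free ground truth.

    ``pixels`` holds intensities in [0, 1]; ``class_map`` the per-pixel label
    (0 background, 1 gum, 2 tooth) of the underlying noise-free rendering.
    """

    pixels: np.ndarray
    class_map: np.ndarray
    stage: int
    age_months: int
    seed: int

    def __post_init__(self):
        if self.pixels.shape != self.class_map.shape:
            raise ValueError("pixels and class_map must have identical shape")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if age_to_stage(self.age_months) != self.stage:
            raise ValueError(
                f"stage {self.stage} inconsistent with age {self.age_months} months"
            )


@dataclass(frozen=True)
class CorruptionMask:
    """Boolean missing-pixel mask (True = missing) with its provenance."""

    mask: np.ndarray
    kind: str
    target_fraction: float
    seed: int

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


def age_to_stage(age_months: int) -> int:
    """Map an age in months to the developmental stage 1..6.

    Brackets are left-closed: 1:[24,48), 2:[48,72), 3:[72,96), 4:[96,120),
    5:[120,144), 6:[144,168].
    """
    if not (AGE_MIN <= age_months <= AGE_MAX):
        raise ValueError(
            f"age_months={age_months} outside the supported span "
            f"[{AGE_MIN}, {AGE_MAX}] months (2-14 years)"
        )
    if age_months == AGE_MAX:
        return 6
    return 1 + (int(age_months) - AGE_MIN) // 24


def stage_to_age(stage: int) -> int:
    """Representative age (bracket midpoint, months) for a stage."""
    lo, hi = STAGE_AGE_BRACKETS[stage]
    return (lo + hi) // 2


def _arch_params(height: int, width: int):
    x_left, x_right = 0.12 * width, 0.88 * width
    xc = 0.5 * width
    y_apex, y_end = 0.40 * height, 0.66 * height
    curv = (y_end - y_apex) / (x_right - xc) ** 2
    return x_left, x_right, xc, y_apex, curv


def _arch_y(x, height, width):
    _, _, xc, y_apex, curv = _arch_params(height, width)
    return y_apex + curv * (x - xc) ** 2


def expected_tooth_geometry(stage: int, size: Tuple[int, int]):
    """Analytic per-stage tooth geometry: (rendered count, semi-axes a, b,
    expected total tooth area in pixels). Used by tests as an area oracle."""
    m = STAGE_MORPHOLOGY[stage]
    height, width = size
    x_left, x_right, *_ = _arch_params(height, width)
    n = m["n_teeth"]
    spacing = (x_right - x_left) / n
    a = min(0.33 * spacing, m["size_rel"] * min(height, width))
    b = 1.5 * a
    n_missing = round(m["missing_frac"] * n)
    n_rendered = n - n_missing
    n_partial = round(m["partial_frac"] * n_rendered)
    area = np.pi * a * b * (n_rendered - 0.5 * n_partial)
    return n_rendered, a, b, area


def generate_phantom(
    stage: int,
    size: Tuple[int, int] = (64, 64),
    seed: int = 0,
    noise_sd: float = 0.02,
) -> Phantom:
    """Render a stage-parameterized dental phantom.

    Teeth are filled ellipses along a parabolic arch; a gum band borders the
    arch; the background is darkest and teeth brightest. ``class_map`` is the
    noise-free ground truth; zero-mean Gaussian noise with sd ``noise_sd`` is
    added to the intensities and clipped to [0, 1].
    """
    if stage not in STAGE_MORPHOLOGY:
        raise ValueError(f"stage must be in 1..6, got {stage}")
    height, width = size
    if height < 32 or width < 32:
        raise ValueError(f"size must be at least 32x32, got {size}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    m = STAGE_MORPHOLOGY[stage]
    x_left, x_right, xc, y_apex, curv = _arch_params(height, width)

    n = m["n_teeth"]
    spacing = (x_right - x_left) / n
    a = min(0.33 * spacing, m["size_rel"] * min(height, width))
    b = 1.5 * a

    n_missing = round(m["missing_frac"] * n)
    slots = np.arange(n)
    missing = set(rng.choice(slots, size=n_missing, replace=False).tolist())
    rendered = [i for i in slots if i not in missing]
    n_partial = round(m["partial_frac"] * len(rendered))
    partial = set(
        rng.choice(np.array(rendered), size=n_partial, replace=False).tolist()
    )

    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    class_map = np.full(size, BACKGROUND, dtype=np.uint8)

    # gum band: within a vertical half-width of the arch curve
    gum_h = max(1.5, 0.05 * height)
    arch = _arch_y(cols.astype(float), height, width)
    in_span = (cols >= x_left - 2) & (cols <= x_right + 2)
    class_map[(np.abs(rows - arch) <= gum_h) & in_span] = GUM

    for i in slots:
        if i in missing:
            continue
        tx = x_left + spacing * (i + 0.5)
        ty = _arch_y(tx, height, width)
        ell = ((cols - tx) / max(a, 0.6)) ** 2 + ((rows - ty) / max(b, 0.9)) ** 2 <= 1.0
        if i in partial:  # half-erupted: lower half of the crown only
            ell &= rows >= ty
        ell[int(round(ty)) % height, int(round(tx)) % width] = True
        class_map[ell] = TOOTH

    pixels = np.empty(size, dtype=np.float64)
    for cls, val in CLASS_INTENSITY.items():
        pixels[class_map == cls] = val
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=size)
    pixels = np.clip(pixels, 0.0, 1.0)

    return Phantom(
        pixels=pixels,
        class_map=class_map,
        stage=stage,
        age_months=stage_to_age(stage),
        seed=seed,
    )


def corrupt(
    pixels: np.ndarray,
    kind: str = "blobs",
    target_fraction: float = 0.2,
    seed: int = 0,
) -> Tuple[np.ndarray, CorruptionMask]:
    """Knock out pixels, returning (corrupted, mask).

    Masked pixels are set to a sentinel fill of 0; consumers must consult the
    boolean mask, never the sentinel. ``target_fraction`` must stay below 0.9
    so hole boundaries retain known neighbors for imputation.
    """
    if not (0.0 <= target_fraction < 0.9):
        raise ValueError(
            f"target_fraction must be in [0, 0.9), got {target_fraction}"
        )
    if kind not in CORRUPTION_KINDS:
        raise ValueError(f"kind must be one of {CORRUPTION_KINDS}, got {kind!r}")
    rng = np.random.default_rng(seed)
    h, w = pixels.shape
    if target_fraction == 0.0:
        mask = np.zeros_like(pixels, dtype=bool)
    elif kind == "bernoulli":
        mask = rng.random(pixels.shape) < target_fraction
    elif kind == "blobs":
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.standard_normal(pixels.shape), sigma=max(h, w) / 16)
        thresh = np.quantile(field, 1.0 - target_fraction)
        mask = field > thresh
    else:  # rectangles
        mask = np.zeros_like(pixels, dtype=bool)
        for _ in range(1000):
            deficit = target_fraction - mask.mean()
            if deficit <= 0.005:
                break
            side = int(np.clip(np.sqrt(deficit * h * w), 2, max(h, w) // 4))
            r0 = int(rng.integers(0, h - side + 1))
            c0 = int(rng.integers(0, w - side + 1))
            mask[r0 : r0 + side, c0 : c0 + side] = True
    corrupted = np.where(mask, 0.0, pixels)
    return corrupted, CorruptionMask(
        mask=mask, kind=kind, target_fraction=target_fraction, seed=seed
    )


def segment_classes(
    pixels: np.ndarray,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Three-class intensity thresholding into background/gum/tooth.

    Used only when a ground-truth class map is unavailable. ``thresholds``
    (a, b) label intensity < a background, a <= intensity < b gum, and
    intensity >= b tooth.
    """
    a, b = thresholds
    if a >= b:
        raise ValueError(f"thresholds must satisfy a < b, got a={a}, b={b}")
    class_map = np.full(pixels.shape, BACKGROUND, dtype=np.uint8)
    class_map[pixels >= a] = GUM
    class_map[pixels >= b] = TOOTH
    return class_map
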