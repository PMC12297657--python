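"""Onion-peel scheduling shared by the GAPI and DTBR imputers.

A hole is filled from its boundary inward: each peel imputes every masked
pixel that currently has at least one known 8-neighbor, in descending order
of known-neighbor count with row-major tie-breaks, and pixels imputed in one
peel count as known in the next. Within a peel all reads come from the
peel-start snapshot, so the schedule is fully deterministic and independent
of traversal order.
"""

from __future__ import annotations

from typing import Callable, List, Tuple

import numpy as np
from scipy.ndimage import correlate

_NEIGHBOR_KERNEL = np.ones((3, 3))
_NEIGHBOR_KERNEL[1, 1] = 0

# (dr, dc) offsets of the 8-connected neighborhood, row-major.
NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def known_neighbor_counts(known: np.ndarray) -> np.ndarray:
    """Number of known 8-neighbors per pixel (image borders truncate)."""
    return correlate(known.astype(float), _NEIGHBOR_KERNEL, mode="constant").round().astype(int)


def peel_order(known: np.ndarray, masked: np.ndarray) -> List[Tuple[int, int]]:
    """Coordinates of this peel: masked pixels with >=1 known neighbor,
    descending known-neighbor count, ties row-major."""
    counts = known_neighbor_counts(known)
    rr, cc = np.nonzero(masked & (counts > 0))
    order = np.lexsort((cc, rr, -counts[rr, cc]))
    return list(zip(rr[order].tolist(), cc[order].tolist()))


def onion_peel(
    pixels: np.ndarray,
    mask: np.ndarray,
    fill_peel: Callable[[np.ndarray, np.ndarray, List[Tuple[int, int]]], np.ndarray],
) -> Tuple[np.ndarray, List[int]]:
    """Run the peel schedule to completion.

    ``fill_peel(image_snapshot, known_snapshot, coords)`` returns the imputed
    value per coordinate; masked pixels hold the sentinel 0 until filled.
    Returns the completed image and the per-peel pixel counts.
    """
    if pixels.shape != mask.shape:
        raise ValueError("pixels and mask must share a shape")
    if mask.all():
        raise ValueError(
            "no boundary information: every pixel is masked, nothing to impute from"
        )
    out = np.where(mask, 0.0, pixels.astype(np.float64))
    known = ~mask.astype(bool)
    remaining = mask.astype(bool).copy()
    peel_counts: List[int] = []
    while remaining.any():
        coords = peel_order(known, remaining)
        if not coords:  # unreachable given the mask.all() guard
            raise RuntimeError("isolated masked region with no known boundary")
        snapshot = out.copy()
        known_snapshot = known.copy()
        values = fill_peel(snapshot, known_snapshot, coords)
        for (r, c), v in zip(coords, values):
            out[r, c] = v
            known[r, c] = True
            remaining[r, c] = False
        peel_counts.append(len(coords))
    return out, peel_counts
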