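"""File I/O: images, array archives, and reproducibility manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import imageio.v3 as iio
import numpy as np


def save_image(path, pixels: np.ndarray, bit_depth: int = 8) -> None:
    """Write [0,1] intensities as an 8- or 16-bit PNG/TIFF."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(np.clip(pixels, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, arr)


def load_image(path) -> np.ndarray:
    """Read a grayscale image and map it to [0, 1] floats."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse any color channels
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    out = arr.astype(np.float64)
    if out.max() > 1.0:
        out /= out.max()
    return out


def save_arrays(path, **arrays) -> None:
    np.savez_compressed(path, **arrays)


def load_arrays(path) -> dict:
    with np.load(path) as arc:
        return {k: arc[k] for k in arc.files}


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    outdir, subcommand: str, params: Dict, seed: Optional[int] = None, inputs=()
) -> Path:
    """JSON run manifest: parameters, seed, and input hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "params": params,
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "version": __version__,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
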