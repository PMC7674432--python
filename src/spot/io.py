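"""File formats: TIFF maps, JSON manifests, YAML configs, PNG exports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile


def write_map_tiff(image: np.ndarray, path) -> Path:
    """Write a 2D (or paged 3D) map as 32-bit float TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def read_map_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_mask_tiff(mask: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    return path


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
    return path


def orientation_to_hsv_png(orientation: np.ndarray, intensity: np.ndarray, path) -> Path:
    """Export an orientation map as an HSV-coded PNG.

    Hue encodes the dipole angle (pi-periodic, full hue wheel over [0, pi)),
    value encodes normalized intensity, saturation is 1.
    """
    from matplotlib.colors import hsv_to_rgb
    from matplotlib.image import imsave

    phi = np.mod(np.asarray(orientation, dtype=float), np.pi)
    inten = np.asarray(intensity, dtype=float)
    vmax = inten.max() if inten.size and inten.max() > 0 else 1.0
    hsv = np.stack(
        [phi / np.pi, np.ones_like(phi), np.clip(inten / vmax, 0.0, 1.0)], axis=-1
    )
    path = Path(path)
    imsave(path, hsv_to_rgb(hsv))
    return path


def ratio_to_colormap_png(ratio: np.ndarray, path, cmap: str = "hot",
                          vmin: float | None = None, vmax: float | None = None) -> Path:
    """Export a polarity (or depth) map with a warm colormap; NaNs render black."""
    from matplotlib import colormaps
    from matplotlib.image import imsave

    data = np.asarray(ratio, dtype=float)
    finite = np.isfinite(data)
    lo = vmin if vmin is not None else (data[finite].min() if finite.any() else 0.0)
    hi = vmax if vmax is not None else (data[finite].max() if finite.any() else 1.0)
    norm = np.zeros_like(data)
    if hi > lo:
        norm = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    rgba = colormaps[cmap](norm)
    rgba[~finite] = (0.0, 0.0, 0.0, 1.0)
    path = Path(path)
    imsave(path, rgba)
    return path
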