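"""Bead-based channel registration and illumination flat-field correction.

Before each experiment a slide of sub-diffraction fluorescent beads is imaged:
the same beads appear in every spectral channel, so localizing them and
fitting a 2D affine transform registers the channels; a densely covered bead
slide also samples the illumination envelope, whose smoothed, unit-mean
version is divided out of all six raw frames (flat-fielding).

Coordinates are (x, y) with x = column, y = row, 0-based, pixel-center
convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .optics_sim import RawSPOTStack

__all__ = [
    "AffineTransform2D",
    "EmitterLocalizations",
    "FlatFieldMap",
    "localize_emitters",
    "fit_affine",
    "apply_transform",
    "estimate_flatfield",
    "correct_flatfield",
]

log = logging.getLogger(__name__)

_COORD_CONVENTION = "xy, row-major 2x3, 0-based pixel centers"


@dataclass
class AffineTransform2D:
    """2D affine map (x', y') = A (x, y) + t, pixel units.

    ``matrix`` is 2x3: linear part in the first two columns, translation in
    the last.  ``rms`` optionally records the fit residual.
    """

    matrix: np.ndarray
    rms: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(self.det) <= 1e-6:
            raise ValueError("affine linear part is (near-)singular")

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix[:, :2]))

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform2D":
        a = np.linalg.inv(self.matrix[:, :2])
        t = -a @ self.matrix[:, 2]
        return AffineTransform2D(np.column_stack([a, t]))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "matrix": self.matrix.ravel().tolist(),
                    "convention": _COORD_CONVENTION,
                    "rms": self.rms,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "AffineTransform2D":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["matrix"], dtype=float).reshape(2, 3), rms=d.get("rms"))


@dataclass
class EmitterLocalizations:
    """Sub-pixel emitter positions (N x 2, xy) with peak intensities."""

    coords: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class FlatFieldMap:
    """Strictly positive, unit-mean illumination-envelope image."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("flat-field map must be a 2D image")
        if not np.all(self.data > 0):
            raise ValueError("flat-field map must be strictly positive")
        if abs(self.data.mean() - 1.0) > 1e-6:
            raise ValueError("flat-field map must have unit mean (normalize first)")


def localize_emitters(image: np.ndarray, intensity_threshold: float) -> EmitterLocalizations:
    """Threshold + connected components + intensity-weighted centroid.

    Each connected component above threshold yields one localization; the
    centroid is taken over the component plus a 1-pixel dilation ring so the
    sub-threshold skirt of the spot still contributes.  No component above
    threshold is not an error — the result is simply empty.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    labels, nlab = ndimage.label(image > intensity_threshold)
    coords, peaks = [], []
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    for lab in range(1, nlab + 1):
        region = ndimage.binary_dilation(labels == lab)
        w = image[region]
        total = w.sum()
        if total <= 0:
            continue
        coords.append([(xx[region] * w).sum() / total, (yy[region] * w).sum() / total])
        peaks.append(image[labels == lab].max())
    return EmitterLocalizations(
        np.array(coords) if coords else np.empty((0, 2)), np.array(peaks)
    )


def _mutual_nearest_pairs(
    src: np.ndarray, dst: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    tree_s, tree_d = cKDTree(src), cKDTree(dst)
    d_sd, j_sd = tree_d.query(src, distance_upper_bound=radius)
    _, j_ds = tree_s.query(dst, distance_upper_bound=radius)
    pairs = [
        (i, j)
        for i, (d, j) in enumerate(zip(d_sd, j_sd))
        if np.isfinite(d) and j < len(dst) and j_ds[j] == i
    ]
    if not pairs:
        return np.empty((0, 2)), np.empty((0, 2))
    si, di = zip(*pairs)
    return src[list(si)], dst[list(di)]


def fit_affine(
    src: EmitterLocalizations | np.ndarray,
    dst: EmitterLocalizations | np.ndarray,
    match_radius: float = 5.0,
) -> AffineTransform2D:
    """Least-squares 2D affine from mutually-nearest-neighbor bead pairs.

    Unmatched points are dropped (count logged).  Requires at least three
    non-collinear pairs.
    """
    s = src.coords if isinstance(src, EmitterLocalizations) else np.asarray(src, float)
    d = dst.coords if isinstance(dst, EmitterLocalizations) else np.asarray(dst, float)
    if len(s) == 0 or len(d) == 0:
        raise ValueError("need localizations in both channels")
    ps, pd = _mutual_nearest_pairs(s, d, match_radius)
    dropped = len(s) - len(ps)
    if dropped:
        log.info("fit_affine: dropped %d unmatched source points", dropped)
    if len(ps) < 3:
        raise ValueError(f"only {len(ps)} matched pairs; at least 3 required")
    centered = ps - ps.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("matched bead configuration is collinear (degenerate geometry)")
    A = np.column_stack([ps, np.ones(len(ps))])
    coeff, *_ = np.linalg.lstsq(A, pd, rcond=None)
    matrix = coeff.T  # 2x3
    resid = A @ coeff - pd
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return AffineTransform2D(matrix, rms=rms)


def apply_transform(image: np.ndarray, transform: AffineTransform2D) -> np.ndarray:
    """Resample ``image`` through the transform: out(x) = image(T(x)).

    Bilinear interpolation, zeros outside the input, shape preserved.  Used
    to pull the second channel onto the reference channel's grid given the
    reference-to-second transform.
    """
    image = np.asarray(image, dtype=float)
    m = transform.matrix
    # ndimage maps output (row, col) -> input coordinates; convert xy -> rc.
    matrix_rc = np.array([[m[1, 1], m[1, 0]], [m[0, 1], m[0, 0]]])
    offset = (m[1, 2], m[0, 2])
    return ndimage.affine_transform(
        image, matrix_rc, offset=offset, order=1, mode="constant", cval=0.0
    )


def estimate_flatfield(calibration_images, sigma: float | None = None) -> FlatFieldMap:
    """Smoothed, unit-mean illumination envelope from bead-slide images.

    The mean of the inputs is blurred with a large Gaussian kernel (default
    sigma = image size / 8) to suppress individual beads and keep only the
    slowly varying illumination envelope.
    """
    images = [np.asarray(im, dtype=float) for im in calibration_images]
    if not images:
        raise ValueError("at least one calibration image is required")
    mean_img = np.mean(images, axis=0)
    if mean_img.mean() <= 0:
        raise ValueError("calibration images have non-positive mean")
    if sigma is None:
        sigma = max(mean_img.shape) / 8.0
    envelope = ndimage.gaussian_filter(mean_img, sigma, mode="reflect")
    envelope = np.clip(envelope, np.finfo(float).tiny, None)
    return FlatFieldMap(envelope / envelope.mean())


def correct_flatfield(stack: RawSPOTStack, flatfield: FlatFieldMap) -> RawSPOTStack:
    """Divide all six frames (every channel) by the unit-mean envelope."""
    if flatfield.data.shape != stack.frames.shape[-2:]:
        raise ValueError(
            f"flat-field shape {flatfield.data.shape} does not match "
            f"frame shape {stack.frames.shape[-2:]}"
        )
    return RawSPOTStack(stack.frames / flatfield.data, stack.config, meta=dict(stack.meta))
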