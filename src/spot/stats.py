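"""Measurement utilities on reconstructed maps.

Organelle-level readout mirrors how the maps are used in practice: polylines
traced on the intensity image are sampled on the emission-ratio and
modulation-depth maps; repeated acquisitions are accepted only if they agree
to within a fluctuation bound; organelle groups are summarized by sigma /
2-sigma covariance ellipses on the polarity-phase plane; and round-shaped
compartments are classified by the exclusive-ellipse rule (a point must fall
inside exactly one group's sigma contour to receive its label).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PolylineMeasurement",
    "GroupEllipse",
    "sample_polyline",
    "repeat_acceptance",
    "fit_group_ellipse",
    "classify_compartment",
    "save_ellipses",
    "load_ellipses",
]


@dataclass
class PolylineMeasurement:
    """Values sampled along a polyline band, with summary statistics."""

    vertices: np.ndarray
    halfwidth: float
    values: np.ndarray
    mean: float
    sd: float
    n: int


@dataclass
class GroupEllipse:
    """Mean and covariance of one organelle group on the polarity-phase plane.

    The sigma contour is the Mahalanobis-distance-1 ellipse of the sample
    covariance; 2-sigma is distance 2.
    """

    label: str
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise ValueError("covariance must be positive definite")

    def mahalanobis(self, point) -> float:
        d = np.asarray(point, dtype=float).reshape(2) - self.mean
        return float(np.sqrt(d @ np.linalg.solve(self.covariance, d)))

    def contains(self, point, n_sigma: float = 1.0) -> bool:
        return self.mahalanobis(point) <= n_sigma

    def contour(self, n_sigma: float = 1.0, n_points: int = 100) -> np.ndarray:
        """Points on the n-sigma contour, for plotting."""
        t = np.linspace(0.0, 2.0 * np.pi, n_points)
        circle = np.stack([np.cos(t), np.sin(t)])
        root = np.linalg.cholesky(self.covariance)
        return (self.mean[:, None] + n_sigma * root @ circle).T


def sample_polyline(
    map_image: np.ndarray,
    mask: np.ndarray | None,
    polyline: np.ndarray,
    halfwidth: float = 0.0,
) -> PolylineMeasurement:
    """Sample a map along a polyline with a perpendicular averaging band.

    Steps along the polyline at 1-pixel arc-length increments; at each step
    the perpendicular offsets -halfwidth..halfwidth (1-pixel spacing) are
    read by nearest-pixel lookup, skipping masked or out-of-bounds pixels.
    Raises if nothing measurable remains.
    """
    img = np.asarray(map_image, dtype=float)
    verts = np.asarray(polyline, dtype=float).reshape(-1, 2)
    if len(verts) < 2:
        raise ValueError("polyline needs at least two vertices")
    valid = np.isfinite(img)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)

    samples: list[float] = []
    n_off = int(np.floor(halfwidth))
    for a, b in zip(verts[:-1], verts[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        if length == 0:
            continue
        direction = seg / length
        normal = np.array([-direction[1], direction[0]])
        for step in np.arange(0.0, length + 0.5, 1.0):
            base = a + min(step, length) * direction
            for off in range(-n_off, n_off + 1):
                x, y = base + off * normal
                px, py = int(round(x)), int(round(y))
                if 0 <= py < img.shape[0] and 0 <= px < img.shape[1] and valid[py, px]:
                    samples.append(img[py, px])
    if not samples:
        raise ValueError("nothing measurable: all polyline samples are masked")
    values = np.asarray(samples)
    return PolylineMeasurement(
        vertices=verts,
        halfwidth=halfwidth,
        values=values,
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        n=len(values),
    )


def repeat_acceptance(values) -> tuple[bool, float]:
    """Accept repeated measurements whose spread is small relative to the mean.

    fluctuation = (max - min) / mean; accepted iff fluctuation <= 0.15
    (inclusive).  Scale-invariant: multiplying all values by c > 0 leaves the
    decision unchanged.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("at least two repeated measurements are required")
    if not np.all(np.isfinite(vals)):
        raise ValueError("measurements must be finite")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("mean of measurements is zero; fluctuation undefined")
    fluctuation = float((vals.max() - vals.min()) / mean)
    return fluctuation <= 0.15, fluctuation


def fit_group_ellipse(points, label: str = "") -> GroupEllipse:
    """Sample mean and covariance of (ratio, depth) points as a GroupEllipse."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("at least three points are required")
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.any(np.linalg.eigvalsh(cov) <= 1e-15 * max(np.abs(cov).max(), 1.0)):
        raise ValueError("degenerate (collinear) point configuration")
    return GroupEllipse(label=label, mean=pts.mean(axis=0), covariance=cov)


def classify_compartment(point, ellipses) -> str:
    """Exclusive-ellipse classification on the polarity-phase plane.

    Returns the group label iff the point lies within exactly one group's
    sigma contour; ``"ambiguous"`` if inside two or more (e.g. overlapping
    Golgi / late-endosome groups); ``"unassigned"`` if inside none.
    Independent of the order of the ellipse list.
    """
    ellipses = list(ellipses)
    if not ellipses:
        raise ValueError("at least one group ellipse is required")
    hits = [e.label for e in ellipses if e.contains(point, n_sigma=1.0)]
    if len(hits) == 1:
        return hits[0]
    return "ambiguous" if hits else "unassigned"


def save_ellipses(ellipses, path) -> None:
    payload = [
        {
            "label": e.label,
            "mean": e.mean.tolist(),
            "covariance": e.covariance.tolist(),
        }
        for e in ellipses
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_ellipses(path) -> list[GroupEllipse]:
    payload = json.loads(Path(path).read_text())
    return [
        GroupEllipse(label=d["label"], mean=d["mean"], covariance=d["covariance"])
        for d in payload
    ]
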