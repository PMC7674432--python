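"""Emission-ratio (lipid polarity) mapping from two spectral channels.

A solvatochromic dye such as Nile Red red-shifts in polar lipid environments,
so the quotient of a longer-wavelength over a shorter-wavelength detection
channel rises with lipid polarity.  The ratio is taken pixel-wise on
registered, flat-field-corrected, sectioned channel images and masked where
the denominator is too dim to divide meaningfully.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PolarityMap", "emission_ratio_map"]


@dataclass
class PolarityMap:
    """Dimensionless numerator/denominator ratio image with validity mask."""

    ratio: np.ndarray
    mask: np.ndarray
    numerator_label: str = "red"
    denominator_label: str = "green"


def emission_ratio_map(
    numerator: np.ndarray,
    denominator: np.ndarray,
    threshold: float = 0.0,
    numerator_label: str = "red",
    denominator_label: str = "green",
) -> PolarityMap:
    """Pixel-wise channel quotient where the denominator exceeds threshold.

    Masked pixels carry NaN in the ratio image; no division is performed
    there.  Dividing both channels by a common gain leaves the ratio
    unchanged, so the map is insensitive to overall excitation intensity.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError(f"channel shapes differ: {num.shape} vs {den.shape}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = den > threshold
    ratio = np.full(num.shape, np.nan)
    np.divide(num, den, out=ratio, where=mask)
    return PolarityMap(
        ratio=ratio,
        mask=mask,
        numerator_label=numerator_label,
        denominator_label=denominator_label,
    )
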