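"""Dipole orientation and modulation depth from three polarization images.

Under linear excitation at angle theta a wobbling dipole of orientation phi
and modulation depth m fluoresces proportionally to

    I(theta) = a0 (1 + m cos(2 (theta - phi))).

With three equally spaced excitation angles the +/-1st circular harmonics on
the polarization dimension recover (m, phi) exactly:

    a0 = (1/3) sum_k I_k
    a1 = (2/3) sum_k I_k exp(-2i theta_k)      ->  |a1| = a0 m,
    phi = (-arg a1 / 2) mod pi.

Exactness holds because both sum_k exp(-2i theta_k) and
sum_k exp(-4i theta_k) vanish for equally spaced angles; unequally spaced
angle sets are rejected to preserve this contract.  Modulation depth is the
lipid-phase readout (ordered membranes restrict dipole wobble, raising m);
orientation maps the ensemble dipole axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sectioning import SectionedStack

__all__ = ["PolarizationMaps", "polarization_harmonics", "validity_mask"]


@dataclass
class PolarizationMaps:
    """Per-pixel harmonic decomposition of the polarization response.

    ``modulation`` is clipped to [0, 1]; ``modulation_raw`` keeps the
    unclipped |a1|/a0 for validity screening.  ``orientation`` is in
    [0, pi) radians from the +x image axis.
    """

    a0: np.ndarray
    a1: np.ndarray
    modulation: np.ndarray
    orientation: np.ndarray
    mask: np.ndarray
    modulation_raw: np.ndarray


def polarization_harmonics(sectioned, theta_exc) -> PolarizationMaps:
    """Compute (a0, a1, m, phi) maps from three polarization-modulated images.

    Parameters
    ----------
    sectioned : SectionedStack or array of shape (3, H, W)
        One image per excitation polarization.
    theta_exc : sequence of three floats
        The excitation polarization angles (pattern direction plus the
        s-polarization offset), radians; must be equally spaced modulo pi.
    """
    images = sectioned.images if isinstance(sectioned, SectionedStack) else np.asarray(
        sectioned, dtype=float
    )
    if images.ndim != 3 or images.shape[0] != 3:
        raise ValueError("expected three images, shape (3, H, W)")
    theta = np.asarray(theta_exc, dtype=float)
    if theta.shape != (3,):
        raise ValueError("exactly three excitation angles are required")
    # The estimator is exact iff the second and fourth harmonics of the angle
    # set vanish; this simultaneously enforces distinctness.
    if (
        abs(np.exp(-2j * theta).sum()) > 1e-9
        or abs(np.exp(-4j * theta).sum()) > 1e-9
    ):
        raise ValueError(
            "excitation angles must be three equally spaced angles modulo pi "
            "(e.g. 0, 60, 120 degrees)"
        )

    a0 = images.mean(axis=0)
    phasors = np.exp(-2j * theta)
    a1 = (2.0 / 3.0) * np.tensordot(phasors, images, axes=(0, 0))

    positive = a0 > 0
    m_raw = np.zeros_like(a0)
    np.divide(np.abs(a1), a0, out=m_raw, where=positive)
    orientation = np.mod(-np.angle(a1) / 2.0, np.pi)
    orientation[~positive] = 0.0
    return PolarizationMaps(
        a0=a0,
        a1=a1,
        modulation=np.clip(m_raw, 0.0, 1.0),
        orientation=orientation,
        mask=positive,
        modulation_raw=m_raw,
    )


def validity_mask(
    maps: PolarizationMaps, intensity_threshold: float, m_tolerance: float = 0.1
) -> PolarizationMaps:
    """Keep pixels bright enough and physically consistent.

    A pixel survives iff ``a0 > intensity_threshold`` and the raw modulation
    does not exceed 1 by more than ``m_tolerance`` (larger excursions signal
    noise-dominated harmonics rather than a dipole response).
    """
    if intensity_threshold < 0:
        raise ValueError("intensity_threshold must be >= 0")
    mask = (maps.a0 > intensity_threshold) & (maps.modulation_raw <= 1.0 + m_tolerance)
    return PolarizationMaps(
        a0=maps.a0,
        a1=maps.a1,
        modulation=np.where(mask, np.clip(maps.modulation_raw, 0.0, 1.0), 0.0),
        orientation=maps.orientation,
        mask=mask,
        modulation_raw=maps.modulation_raw,
    )
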