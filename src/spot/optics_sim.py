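"""Physics forward model for SPOT acquisition.

SPOT (spectrum and polarization optical tomography) records six raw frames —
three sinusoidal illumination pattern directions, two phases per direction
shifted by pi — in two or more spectral channels.  This module renders those
frames for scenes of point dipole emitters, so that every downstream stage
(registration, flat-fielding, HiLo sectioning, ratiometric and harmonic
analysis) can be exercised and validated without experimental data.

Model summary
-------------
* Detection PSF: separable Gaussian, ``exp(-4 ln2 ((dx^2+dy^2)/FWHM_lat^2))
  * exp(-4 ln2 dz^2/FWHM_ax^2)`` — peak response of an emitter offset from a
  pixel's line of sight by (dx, dy) laterally and dz axially.
* Excitation: s-polarized interfering beams produce a sinusoidal intensity
  pattern whose in-plane polarization is perpendicular to the pattern
  wavevector.  An emitter with in-plane dipole axis phi and wobble-limited
  modulation depth m responds to polarization angle theta with
  ``1 + m cos(2 (theta - phi))``.
* The pattern contrast seen by an emitter decays with defocus like the axial
  response, ``M(z) = exp(-4 ln2 z^2 / FWHM_ax^2)`` — the illumination is
  projected through the same optics, which is precisely why structured
  illumination carries optical-sectioning information.
* Spectral splitting: each emitter's photons are divided between the two
  detection channels so that their quotient equals the emitter's emission
  ratio rho (a solvatochromic-shift proxy for lipid polarity).

Only excitation is polarization modulated; detection is treated as
polarization insensitive.  Dipoles are confined to the sample plane.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DipoleEmitter",
    "OpticalConfig",
    "RawSPOTStack",
    "excitation_response",
    "psf_weight",
    "pattern_contrast",
    "channel_weights",
    "render_spot_stack",
    "render_uniform_plane",
    "add_noise",
    "generate_bead_field",
]

_FOUR_LN2 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class DipoleEmitter:
    """Ground-truth point source.

    Parameters
    ----------
    x, y, z : float
        Position in nm, sample coordinates; ``z = 0`` is the focal plane,
        x increases to the right, y downward (image convention).
    brightness : float
        Expected photons per uniformly illuminated frame (summed over the
        two spectral channels under the equal-total split convention).
    emission_ratio : float
        Quotient numerator-channel / denominator-channel of the emitter's
        emission, ``rho > 0``.
    orientation : float
        In-plane dipole axis angle from +x, radians; stored in [0, pi).
    wobble : float
        Polarization modulation depth ``m`` in [0, 1]; 1 is an ideal fixed
        dipole, 0 a free rotor.
    """

    x: float
    y: float
    z: float = 0.0
    brightness: float = 1000.0
    emission_ratio: float = 1.0
    orientation: float = 0.0
    wobble: float = 1.0

    def __post_init__(self) -> None:
        if not self.emission_ratio > 0:
            raise ValueError(f"emission_ratio must be > 0, got {self.emission_ratio}")
        if not 0.0 <= self.wobble <= 1.0:
            raise ValueError(f"wobble must be in [0, 1], got {self.wobble}")
        if self.brightness < 0:
            raise ValueError(f"brightness must be >= 0, got {self.brightness}")
        object.__setattr__(self, "orientation", float(self.orientation) % math.pi)


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry, optics and noise parameters.

    All lengths in nm.  ``pattern_angles`` are the directions of the three
    illumination pattern wavevectors; the excitation polarization for
    direction k is ``pattern_angles[k] + excitation_polarization_offset``
    (default pi/2: s-polarized beams give a sample-plane field perpendicular
    to the wavevector).
    """

    fwhm_lateral: float = 230.0
    fwhm_axial: float = 670.0
    pixel_size: float = 65.0
    pattern_angles: tuple[float, ...] = (0.0, math.pi / 3.0, 2.0 * math.pi / 3.0)
    pattern_period: float = 230.0
    pattern_phases: tuple[float, float] = (0.0, math.pi)
    excitation_polarization_offset: float = math.pi / 2.0
    channels: tuple[str, ...] = ("red", "green")  # (numerator, denominator)
    channel_split: str = "equal_total"
    channel_gains: tuple[float, ...] | None = None
    background: float = 0.0
    read_noise_sd: float = 0.0
    image_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if len(self.pattern_angles) != 3:
            raise ValueError("exactly three pattern directions are required")
        wrapped = sorted(a % math.pi for a in self.pattern_angles)
        if min(b - a for a, b in zip(wrapped, wrapped[1:])) < 1e-9:
            raise ValueError("pattern directions must be distinct modulo pi")
        for name in ("fwhm_lateral", "fwhm_axial", "pixel_size", "pattern_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        p0, p1 = self.pattern_phases
        if abs(abs(p1 - p0) - math.pi) > 1e-9:
            raise ValueError("the two pattern phases must differ by pi")
        if self.channel_split not in ("equal_total", "equal_denominator"):
            raise ValueError(f"unknown channel_split {self.channel_split!r}")
        if len(self.channels) != 2:
            raise ValueError("two spectral channels (numerator, denominator) expected")

    @property
    def excitation_angles(self) -> tuple[float, ...]:
        off = self.excitation_polarization_offset
        return tuple(a + off for a in self.pattern_angles)

    @property
    def pattern_frequency(self) -> float:
        """Illumination stripe frequency in cycles/pixel."""
        return self.pixel_size / self.pattern_period

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)

    def pixel_grid_nm(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-center coordinates in nm (0-based, x right, y down)."""
        ny, nx = self.image_shape
        x = np.arange(nx, dtype=float) * self.pixel_size
        y = np.arange(ny, dtype=float) * self.pixel_size
        return np.meshgrid(x, y)


@dataclass
class RawSPOTStack:
    """The six raw frames (direction x phase) per spectral channel.

    ``frames`` has shape ``(3, 2, n_channels, H, W)`` indexed
    (direction k, phase p, channel c).
    """

    frames: np.ndarray
    config: OpticalConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 5 or self.frames.shape[:2] != (3, 2):
            raise ValueError(
                "frames must have shape (3 directions, 2 phases, channels, H, W); "
                f"got {self.frames.shape}"
            )

    @property
    def n_channels(self) -> int:
        return self.frames.shape[2]

    def frame(self, direction: int, phase: int, channel: str | int) -> np.ndarray:
        c = channel if isinstance(channel, int) else self.config.channel_index(channel)
        return self.frames[direction, phase, c]

    def phase_averaged(self, channel: str | int) -> np.ndarray:
        """Per-direction uniform-illumination images, shape (3, H, W).

        Averaging the two pi-shifted phases cancels the pattern exactly
        (``1 + M cos`` averages to 1 over a pi shift) for any contrast M.
        """
        c = channel if isinstance(channel, int) else self.config.channel_index(channel)
        return self.frames[:, :, c].mean(axis=1)

    def widefield(self, channel: str | int) -> np.ndarray:
        """Pattern- and polarization-averaged wide-field image."""
        return self.phase_averaged(channel).mean(axis=0)


def excitation_response(theta_exc, phi, m):
    """Fluorescence weight of a wobbling dipole under linear excitation.

    ``1 + m cos(2 (theta_exc - phi))``: mean over polarization angle is 1,
    range [1-m, 1+m], pi-periodic in both angles.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("modulation depth m must be in [0, 1]")
    return 1.0 + m * np.cos(2.0 * (np.asarray(theta_exc, float) - np.asarray(phi, float)))


def psf_weight(dx, dy, dz, config: OpticalConfig):
    """Separable-Gaussian detection weight for an offset (dx, dy, dz) in nm."""
    lat = (np.asarray(dx, float) ** 2 + np.asarray(dy, float) ** 2) / config.fwhm_lateral**2
    ax = np.asarray(dz, float) ** 2 / config.fwhm_axial**2
    return np.exp(-_FOUR_LN2 * (lat + ax))


def pattern_contrast(z, config: OpticalConfig):
    """Illumination pattern modulation contrast at defocus z (nm).

    The pattern is projected through the same optics as the detection path,
    so its contrast decays with the axial response; this decay is what makes
    the structured component a focal-plane marker.
    """
    return np.exp(-_FOUR_LN2 * (np.asarray(z, float) / config.fwhm_axial) ** 2)


def channel_weights(rho: float, convention: str) -> tuple[float, float]:
    """(numerator, denominator) channel fractions for emission ratio rho.

    ``equal_total``: the two channels sum to the emitter brightness —
    (rho/(1+rho), 1/(1+rho)).  ``equal_denominator``: the denominator channel
    receives the full brightness — (rho, 1).
    """
    if convention == "equal_total":
        return rho / (1.0 + rho), 1.0 / (1.0 + rho)
    if convention == "equal_denominator":
        return float(rho), 1.0
    raise ValueError(f"unknown channel-split convention {convention!r}")


def _pattern_wavevector(config: OpticalConfig, k: int) -> tuple[float, float]:
    mag = 2.0 * math.pi / config.pattern_period
    ang = config.pattern_angles[k]
    return mag * math.cos(ang), mag * math.sin(ang)


def render_spot_stack(emitters, config: OpticalConfig) -> RawSPOTStack:
    """Render the noiseless six-frame stack of a dipole-emitter scene.

    Pixel value = background + sum over emitters of
    ``brightness * psf_weight * (1 + M(z) cos(k.x + p)) *
    excitation_response(theta_k + offset, phi, m) * channel_split(rho, c)``
    with the pattern evaluated at the emitter's position (excitation happens
    at the emitter, not at the pixel).
    """
    emitters = list(emitters)
    if not emitters:
        raise ValueError("emitter list must be nonempty")
    ny, nx = config.image_shape
    X, Y = config.pixel_grid_nm()
    frames = np.zeros((3, 2, len(config.channels), ny, nx), dtype=float)
    gains = config.channel_gains or (1.0,) * len(config.channels)

    margin = 3.0 * config.fwhm_lateral
    in_view = [
        e
        for e in emitters
        if -margin <= e.x <= (nx - 1) * config.pixel_size + margin
        and -margin <= e.y <= (ny - 1) * config.pixel_size + margin
    ]
    if not in_view:
        warnings.warn(
            "no emitter lies inside (or near) the field of view; "
            "returning a background-only stack",
            stacklevel=2,
        )

    exc = config.excitation_angles
    for e in in_view:
        patch = e.brightness * psf_weight(X - e.x, Y - e.y, e.z, config)
        contrast = float(pattern_contrast(e.z, config))
        cw = channel_weights(e.emission_ratio, config.channel_split)
        for k in range(3):
            kx, ky = _pattern_wavevector(config, k)
            carrier = kx * e.x + ky * e.y
            resp = float(excitation_response(exc[k], e.orientation, e.wobble))
            for p, phase in enumerate(config.pattern_phases):
                s = 1.0 + contrast * math.cos(carrier + phase)
                for c in range(len(config.channels)):
                    frames[k, p, c] += patch * (s * resp * cw[c] * gains[c])
    frames += config.background
    return RawSPOTStack(frames, config, meta={"emitters": [vars(e).copy() for e in in_view]})


def render_uniform_plane(
    brightness: float,
    z: float,
    config: OpticalConfig,
    emission_ratio: float = 1.0,
    m: float = 0.0,
    phi: float = 0.0,
) -> RawSPOTStack:
    """Render a laterally uniform thin fluorescent plane at defocus z.

    A uniform layer images to a uniform field whose integrated brightness is
    independent of defocus (wide-field microscopy cannot section a uniform
    plane — the missing-cone problem); what defocus removes is the pattern
    contrast, ``M(z) = pattern_contrast(z)``.  The plane's ensemble dipole
    response is parameterized by (m, phi) like a single emitter's.
    """
    ny, nx = config.image_shape
    X, Y = config.pixel_grid_nm()
    frames = np.zeros((3, 2, len(config.channels), ny, nx), dtype=float)
    contrast = float(pattern_contrast(z, config))
    cw = channel_weights(emission_ratio, config.channel_split)
    gains = config.channel_gains or (1.0,) * len(config.channels)
    for k in range(3):
        kx, ky = _pattern_wavevector(config, k)
        resp = float(excitation_response(config.excitation_angles[k], phi, m))
        for p, phase in enumerate(config.pattern_phases):
            s = 1.0 + contrast * np.cos(kx * X + ky * Y + phase)
            for c in range(len(config.channels)):
                frames[k, p, c] = brightness * s * resp * cw[c] * gains[c]
    frames += config.background
    return RawSPOTStack(frames, config, meta={"plane_z_nm": z})


def add_noise(stack: RawSPOTStack, seed: int) -> RawSPOTStack:
    """Poisson shot noise on expected photons plus Gaussian read noise.

    A seed is mandatory — every stochastic result in this package is
    reproducible by construction.  Negative pixels are permitted after read
    noise (as on a baseline-subtracted camera).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible noise")
    rng = np.random.default_rng(seed)
    expected = np.clip(stack.frames, 0.0, None)
    noisy = rng.poisson(expected).astype(float)
    if stack.config.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, stack.config.read_noise_sd, size=noisy.shape)
    meta = dict(stack.meta)
    meta["noise_seed"] = int(seed)
    return RawSPOTStack(noisy, stack.config, meta=meta)


def generate_bead_field(
    n: int,
    transform,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    bead_sigma: float = 1.5,
    brightness: float = 1000.0,
    min_separation: float = 10.0,
    margin: float = 12.0,
):
    """Synthesize a fiducial-bead calibration pair for channel registration.

    Returns ``(image_A, image_B, coords_A, coords_B)`` where image_B renders
    the same beads re-mapped through ``transform`` (an
    ``calibration.AffineTransform2D`` or a 2x3 array, pixel units) and the
    coordinate arrays are the (x, y) ground truth in each channel.  A minimum
    pairwise distance is enforced so the beads stay individually localizable.
    """
    if n < 3:
        raise ValueError("at least 3 beads are required")
    if seed is None:
        raise ValueError("a seed is required")
    matrix = getattr(transform, "matrix", None)
    if matrix is None:
        matrix = np.asarray(transform, dtype=float)
    if matrix.shape != (2, 3):
        raise ValueError("transform must be 2x3 (linear part + translation)")

    rng = np.random.default_rng(seed)
    ny, nx = shape
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not place beads with the requested separation")
        cand = np.array(
            [rng.uniform(margin, nx - 1 - margin), rng.uniform(margin, ny - 1 - margin)]
        )
        if all(np.hypot(*(cand - c)) >= min_separation for c in coords):
            coords.append(cand)
    coords_a = np.array(coords)
    hom = np.column_stack([coords_a, np.ones(n)])
    coords_b = hom @ matrix.T

    inside = (
        (coords_b[:, 0] >= 0)
        & (coords_b[:, 0] <= nx - 1)
        & (coords_b[:, 1] >= 0)
        & (coords_b[:, 1] <= ny - 1)
    )
    if not inside.any():
        raise ValueError("transform maps all beads outside the frame")
    coords_a, coords_b = coords_a[inside], coords_b[inside]

    def render(points: np.ndarray) -> np.ndarray:
        img = np.zeros(shape, dtype=float)
        xs = np.arange(nx, dtype=float)
        ys = np.arange(ny, dtype=float)
        XX, YY = np.meshgrid(xs, ys)
        for px, py in points:
            img += brightness * np.exp(
                -((XX - px) ** 2 + (YY - py) ** 2) / (2.0 * bead_sigma**2)
            )
        return img

    return render(coords_a), render(coords_b), coords_a, coords_b


def _config_to_dict(config: OpticalConfig) -> dict:
    d = vars(config).copy()
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def write_stack(stack: RawSPOTStack, path) -> None:
    """Write a stack as a multi-page TIFF, pages in (direction, phase,
    channel) lexicographic order, with a JSON metadata sidecar."""
    import tifffile

    from pathlib import Path

    path = Path(path)
    k, p, c, h, w = stack.frames.shape
    pages = stack.frames.reshape(k * p * c, h, w).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "page_order": "direction-major, then phase, then channel",
        "shape_kpc": [k, p, c],
        "config": _config_to_dict(stack.config),
        "meta": stack.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=float))


def read_stack(path) -> RawSPOTStack:
    """Read a stack written by :func:`write_stack`."""
    import tifffile

    from pathlib import Path

    path = Path(path)
    pages = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    k, p, c = sidecar["shape_kpc"]
    cfg = sidecar["config"]
    for key in ("pattern_angles", "pattern_phases", "channels", "image_shape"):
        cfg[key] = tuple(cfg[key])
    if cfg.get("channel_gains") is not None:
        cfg["channel_gains"] = tuple(cfg["channel_gains"])
    config = OpticalConfig(**cfg)
    frames = pages.reshape(k, p, c, *pages.shape[-2:])
    return RawSPOTStack(frames, config, meta=sidecar.get("meta", {}))
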