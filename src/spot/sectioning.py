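"""HiLo optical sectioning from pi-phase-shifted structured-illumination pairs.

For each pattern direction the two raw frames are

    I_0  = U (1 + M cos psi),     I_pi = U (1 - M cos psi)

where U is the uniform-illumination image and M the pattern contrast, which
decays with defocus.  The half-sum recovers U; the half-difference D carries
the pattern-modulated, hence in-focus, content.  HiLo fuses the low-frequency
in-focus estimate demodulated from |D| with the high-frequency content of U
(which is in focus by itself — defocus blurs away high frequencies):

    Lo = (pi/2) * lowpass(|D|),   Hi = U - lowpass(U),
    sectioned = max(Hi + alpha * eta * Lo, 0).

The pi/2 factor corrects the mean of a rectified cosine (mean of |cos| is
2/pi); eta equalizes the radially averaged spectral amplitudes of the two
bands at the cutoff frequency so they merge seamlessly.  alpha (default 1)
weights the Lo band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics_sim import OpticalConfig, RawSPOTStack

__all__ = [
    "HiLoParams",
    "SectionedStack",
    "hilo_pair",
    "hilo_sectioned_stack",
    "spot_intensity",
    "sim5_to_pair",
    "hilo_from_sim5",
]

log = logging.getLogger(__name__)

_SQRT_2LN2 = np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class HiLoParams:
    """HiLo fusion parameters.

    ``cutoff`` is the Hi/Lo merge frequency in cycles/pixel; the default
    (``None``) is half the illumination pattern frequency.  ``eta`` is
    computed per image pair, never user-set.
    """

    alpha: float = 1.0
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.cutoff is not None and not 0.0 < self.cutoff < 0.5:
            raise ValueError("cutoff must lie in (0, Nyquist=0.5) cycles/pixel")

    def resolve_cutoff(self, config: OpticalConfig | None = None) -> float:
        if self.cutoff is not None:
            return self.cutoff
        if config is None:
            raise ValueError("cutoff not set and no optical config to derive it from")
        return 0.5 * config.pattern_frequency


@dataclass
class SectionedStack:
    """Three optically sectioned, polarization-modulated direction images."""

    images: np.ndarray
    channel: str = ""
    params: HiLoParams = field(default_factory=HiLoParams)
    eta: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] != 3:
            raise ValueError("expected three direction images, shape (3, H, W)")


def _lowpass(image: np.ndarray, cutoff: float) -> np.ndarray:
    """Gaussian low-pass with spectral sigma cutoff/sqrt(2 ln 2) (amplitude
    1/2 at the cutoff), applied as a real-space Gaussian filter."""
    sigma_f = cutoff / _SQRT_2LN2
    sigma_x = 1.0 / (2.0 * np.pi * sigma_f)
    return ndimage.gaussian_filter(image, sigma_x, mode="reflect")


def _radial_band_amplitude(image: np.ndarray, cutoff: float, rel_bw: float = 0.1) -> float:
    """Mean |FFT| amplitude in the annulus cutoff*(1 +/- rel_bw)."""
    f = np.fft.fft2(image)
    fy = np.fft.fftfreq(image.shape[0])[:, None]
    fx = np.fft.fftfreq(image.shape[1])[None, :]
    r = np.hypot(fx, fy)
    band = (r >= cutoff * (1 - rel_bw)) & (r <= cutoff * (1 + rel_bw))
    if not band.any():
        return float("nan")
    return float(np.abs(f[band]).mean())


def hilo_pair(
    i0: np.ndarray,
    ipi: np.ndarray,
    params: HiLoParams = HiLoParams(),
    config: OpticalConfig | None = None,
    return_eta: bool = False,
):
    """Fuse one pi-shifted frame pair of a single pattern direction.

    The result is invariant to swapping the two inputs (the difference enters
    only through its modulus) and homogeneous of degree one in the input
    intensities.  Clipping at zero is applied last, after fusion.
    """
    i0 = np.asarray(i0, dtype=float)
    ipi = np.asarray(ipi, dtype=float)
    if i0.shape != ipi.shape:
        raise ValueError(f"frame shapes differ: {i0.shape} vs {ipi.shape}")
    cutoff = params.resolve_cutoff(config)

    uniform = 0.5 * (i0 + ipi)
    diff = 0.5 * (i0 - ipi)
    lo = _lowpass(np.abs(diff), cutoff) * (np.pi / 2.0)
    hi = uniform - _lowpass(uniform, cutoff)

    a_hi = _radial_band_amplitude(hi, cutoff)
    a_lo = _radial_band_amplitude(lo, cutoff)
    floor = 1e-9 * max(abs(uniform.sum()), 1e-30)  # relative to the DC amplitude
    if not np.isfinite(a_hi) or not np.isfinite(a_lo) or a_lo <= floor or a_hi <= floor:
        eta = 1.0
        log.info("hilo_pair: merge band empty or degenerate; falling back to eta=1")
    else:
        eta = a_hi / a_lo
    fused = np.clip(hi + params.alpha * eta * lo, 0.0, None)
    return (fused, eta) if return_eta else fused


def hilo_sectioned_stack(
    stack: RawSPOTStack, channel: str | int, params: HiLoParams = HiLoParams()
) -> SectionedStack:
    """Apply HiLo to each pattern direction of one spectral channel."""
    images, etas = [], []
    for k in range(3):
        fused, eta = hilo_pair(
            stack.frame(k, 0, channel),
            stack.frame(k, 1, channel),
            params,
            config=stack.config,
            return_eta=True,
        )
        images.append(fused)
        etas.append(eta)
    label = channel if isinstance(channel, str) else stack.config.channels[channel]
    return SectionedStack(np.stack(images), channel=label, params=params, eta=tuple(etas))


def spot_intensity(sectioned: SectionedStack | np.ndarray) -> np.ndarray:
    """SPOT intensity image: pixel-wise mean of the three sectioned images."""
    images = sectioned.images if isinstance(sectioned, SectionedStack) else np.asarray(sectioned)
    if images.ndim != 3 or images.shape[0] != 3:
        raise ValueError("expected exactly three sectioned images")
    return images.mean(axis=0)


def sim5_to_pair(five_phase_images) -> tuple[np.ndarray, np.ndarray]:
    """Adapt a 5-phase SIM direction stack to HiLo inputs.

    The uniform image is the mean of the five phases (a full period of a
    sinusoid averages to a constant); the structured image is the first
    phase.  Returns ``(uniform, structured)``.
    """
    images = [np.asarray(im, dtype=float) for im in five_phase_images]
    if len(images) != 5:
        raise ValueError(f"expected exactly 5 phase images, got {len(images)}")
    if any(im.shape != images[0].shape for im in images):
        raise ValueError("phase images must share one shape")
    uniform = np.mean(images, axis=0)
    return uniform, images[0]


def hilo_from_sim5(
    five_phase_images,
    params: HiLoParams = HiLoParams(),
    config: OpticalConfig | None = None,
) -> np.ndarray:
    """Run HiLo on a 5-phase SIM stack of one direction.

    The complementary-phase frame is synthesized as ``2*uniform - structured``
    so the two-phase code path serves both acquisition modes.
    """
    uniform, structured = sim5_to_pair(five_phase_images)
    return hilo_pair(structured, 2.0 * uniform - structured, params, config=config)
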