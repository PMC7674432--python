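"""End-to-end SPOT reconstruction driver and configuration.

The processing flow mirrors the acquisition-side calibration and the
per-dataset reconstruction: split the camera frame into spectral channel
sub-regions, register the channels with the bead-derived affine transform,
compensate illumination nonuniformity, run HiLo per pattern direction,
average the three sectioned images into the SPOT intensity, divide channels
for the emission-ratio (polarity) map, and run the polarization harmonics
for the modulation-depth (phase) and orientation maps.  Every output is
listed, with a checksum, in a JSON manifest; rerunning on identical inputs
is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as spot_io
from .calibration import AffineTransform2D, FlatFieldMap, apply_transform, correct_flatfield
from .optics_sim import OpticalConfig, RawSPOTStack
from .polarimetry import PolarizationMaps, polarization_harmonics, validity_mask
from .sectioning import HiLoParams, SectionedStack, hilo_sectioned_stack, spot_intensity
from .spectral import PolarityMap, emission_ratio_map

__all__ = [
    "ChannelRegion",
    "ChannelLayout",
    "PipelineConfig",
    "split_channels",
    "assemble_stack",
    "run_reconstruction",
    "ReconstructionResult",
]

log = logging.getLogger(__name__)

PAGE_ORDER = "direction-major, then phase, then channel"


@dataclass(frozen=True)
class ChannelRegion:
    """One spectral channel's rectangular sub-region of the camera frame."""

    label: str
    x0: int
    y0: int
    width: int
    height: int
    band: str = ""


@dataclass
class ChannelLayout:
    """Non-overlapping, equal-size channel sub-regions of one camera frame."""

    regions: list[ChannelRegion]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("layout needs at least one region")
        sizes = {(r.width, r.height) for r in self.regions}
        if len(sizes) != 1:
            raise ValueError("channel regions must all have the same size")
        for i, a in enumerate(self.regions):
            if a.width <= 0 or a.height <= 0 or a.x0 < 0 or a.y0 < 0:
                raise ValueError(f"invalid region {a.label!r}")
            for b in self.regions[i + 1 :]:
                if (
                    a.x0 < b.x0 + b.width
                    and b.x0 < a.x0 + a.width
                    and a.y0 < b.y0 + b.height
                    and b.y0 < a.y0 + a.height
                ):
                    raise ValueError(f"regions {a.label!r} and {b.label!r} overlap")

    def labels(self) -> list[str]:
        return [r.label for r in self.regions]


def split_channels(frame: np.ndarray, layout: ChannelLayout) -> dict[str, np.ndarray]:
    """Crop each channel's sub-region out of a full camera frame."""
    frame = np.asarray(frame)
    out = {}
    for r in layout.regions:
        if r.x0 + r.width > frame.shape[1] or r.y0 + r.height > frame.shape[0]:
            raise ValueError(f"region {r.label!r} exceeds the frame bounds")
        out[r.label] = frame[r.y0 : r.y0 + r.height, r.x0 : r.x0 + r.width]
    return out


def assemble_stack(frames: dict, config: OpticalConfig) -> RawSPOTStack:
    """Build a RawSPOTStack from a {(direction, phase, channel): image} dict,
    reporting exactly which frames are missing."""
    missing = [
        (k, p, c)
        for k in range(3)
        for p in range(2)
        for c in config.channels
        if (k, p, c) not in frames
    ]
    if missing:
        raise ValueError(
            "missing raw frames (direction, phase, channel): "
            + ", ".join(f"(k={k}, phase={'0' if p == 0 else 'pi'}, {c})" for k, p, c in missing)
        )
    first = np.asarray(frames[(0, 0, config.channels[0])])
    arr = np.zeros((3, 2, len(config.channels), *first.shape), dtype=float)
    for k in range(3):
        for p in range(2):
            for ci, c in enumerate(config.channels):
                arr[k, p, ci] = frames[(k, p, c)]
    return RawSPOTStack(arr, config)


@dataclass
class PipelineConfig:
    """Everything the reconstruction driver needs, with explicit thresholds."""

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    hilo: HiLoParams = field(default_factory=HiLoParams)
    ratio_pair: tuple[str, str] = ("red", "green")  # numerator, denominator
    polarimetry_channel: str = "green"
    intensity_threshold: float = 0.0
    m_tolerance: float = 0.1
    denominator_threshold: float = 0.0
    max_registration_rms: float = 1.0
    affine_path: str | None = None
    flatfield_path: str | None = None

    def __post_init__(self) -> None:
        for label in (*self.ratio_pair, self.polarimetry_channel):
            if label not in self.optical.channels:
                raise ValueError(f"channel {label!r} not present in the optical config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        optical_kwargs = raw.pop("optical", {})
        for key in ("pattern_angles", "pattern_phases", "channels", "image_shape",
                    "channel_gains"):
            if key in optical_kwargs and optical_kwargs[key] is not None:
                optical_kwargs[key] = tuple(optical_kwargs[key])
        hilo_kwargs = raw.pop("hilo", {})
        if "ratio_pair" in raw:
            raw["ratio_pair"] = tuple(raw["ratio_pair"])
        return cls(
            optical=OpticalConfig(**optical_kwargs),
            hilo=HiLoParams(**hilo_kwargs),
            **raw,
        )


@dataclass
class ReconstructionResult:
    """In-memory outputs of one reconstruction run."""

    intensity: dict[str, np.ndarray]
    sectioned: dict[str, SectionedStack]
    polarity: PolarityMap
    polarization: PolarizationMaps
    manifest: dict


def run_reconstruction(
    config: PipelineConfig,
    raw: RawSPOTStack,
    transform: AffineTransform2D | None = None,
    flatfield: FlatFieldMap | None = None,
    outdir: str | Path | None = None,
) -> ReconstructionResult:
    """Run the full SPOT reconstruction on one six-frame dataset.

    ``transform`` maps reference-channel coordinates to those of every other
    channel, which is resampled onto the reference grid; a fit residual above
    ``config.max_registration_rms`` aborts with a diagnostic.  When ``outdir``
    is given, all maps, masks, a CSV summary and a checksummed JSON manifest
    are written there deterministically.
    """
    if raw.frames.shape[:2] != (3, 2):
        raise ValueError("raw stack must contain 3 directions x 2 phases")
    optical = raw.config

    if transform is not None:
        if transform.rms is not None and transform.rms > config.max_registration_rms:
            raise ValueError(
                f"registration residual {transform.rms:.3f} px exceeds the "
                f"{config.max_registration_rms} px limit; re-run the bead calibration"
            )
        frames = raw.frames.copy()
        for ci in range(1, frames.shape[2]):  # channel 0 is the reference
            for k in range(3):
                for p in range(2):
                    frames[k, p, ci] = apply_transform(frames[k, p, ci], transform)
        raw = RawSPOTStack(frames, optical, meta=dict(raw.meta))

    if flatfield is not None:
        raw = correct_flatfield(raw, flatfield)

    sectioned: dict[str, SectionedStack] = {}
    intensity: dict[str, np.ndarray] = {}
    for label in optical.channels:
        sec = hilo_sectioned_stack(raw, label, config.hilo)
        sectioned[label] = sec
        intensity[label] = spot_intensity(sec)

    num_label, den_label = config.ratio_pair
    polarity = emission_ratio_map(
        intensity[num_label],
        intensity[den_label],
        threshold=config.denominator_threshold,
        numerator_label=num_label,
        denominator_label=den_label,
    )

    pol = polarization_harmonics(
        sectioned[config.polarimetry_channel], optical.excitation_angles
    )
    pol = validity_mask(pol, config.intensity_threshold, config.m_tolerance)

    manifest: dict = {
        "page_order": PAGE_ORDER,
        "channels": list(optical.channels),
        "ratio_pair": list(config.ratio_pair),
        "polarimetry_channel": config.polarimetry_channel,
        "hilo": {"alpha": config.hilo.alpha,
                 "cutoff": config.hilo.resolve_cutoff(optical),
                 "eta": {c: list(sectioned[c].eta) for c in optical.channels}},
        "thresholds": {
            "intensity": config.intensity_threshold,
            "m_tolerance": config.m_tolerance,
            "denominator": config.denominator_threshold,
        },
        "seeds": {k: v for k, v in raw.meta.items() if "seed" in str(k)},
        "outputs": {},
    }

    result = ReconstructionResult(
        intensity=intensity,
        sectioned=sectioned,
        polarity=polarity,
        polarization=pol,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, config, Path(outdir))
    return result


def _write_outputs(result: ReconstructionResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    for label, img in result.intensity.items():
        files[f"intensity_{label}"] = spot_io.write_map_tiff(
            img, outdir / f"intensity_{label}.tif"
        )
    files["emission_ratio"] = spot_io.write_map_tiff(
        result.polarity.ratio, outdir / "emission_ratio.tif"
    )
    files["emission_ratio_mask"] = spot_io.write_mask_tiff(
        result.polarity.mask, outdir / "emission_ratio_mask.tif"
    )
    files["modulation_depth"] = spot_io.write_map_tiff(
        result.polarization.modulation, outdir / "modulation_depth.tif"
    )
    files["orientation"] = spot_io.write_map_tiff(
        result.polarization.orientation, outdir / "orientation.tif"
    )
    files["polarization_mask"] = spot_io.write_mask_tiff(
        result.polarization.mask, outdir / "polarization_mask.tif"
    )

    rows = []
    for name, img in (
        ("emission_ratio", np.where(result.polarity.mask, result.polarity.ratio, np.nan)),
        ("modulation_depth", np.where(result.polarization.mask,
                                      result.polarization.modulation, np.nan)),
    ):
        finite = np.isfinite(img)
        rows.append(
            {
                "map": name,
                "n_valid": int(finite.sum()),
                "mean": float(np.nanmean(img)) if finite.any() else float("nan"),
                "sd": float(np.nanstd(img)) if finite.any() else float("nan"),
            }
        )
    summary = outdir / "summary.csv"
    pd.DataFrame(rows).to_csv(summary, index=False)
    files["summary"] = summary

    result.manifest["outputs"] = {
        name: {"path": p.name, "sha256": spot_io.sha256_of(p)} for name, p in files.items()
    }
    spot_io.write_json(result.manifest, outdir / "manifest.json")
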