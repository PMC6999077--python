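"""Core data container and on-disk format for dual-channel complex OCT volumes.

A volume is a pair of complex arrays (co- and cross-polarized detection
channels) indexed ``[repeat, y, x, z]`` — repeat index, slow scan axis, fast
scan axis, depth — plus acquisition metadata.  Depth increases posteriorly.

On disk a volume is a directory holding one multi-page 32-bit-float TIFF per
channel (pages alternate real/imaginary plane per B-scan, so any standard
viewer can inspect the data) and a JSON metadata sidecar.  The layout is
deterministic and round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
from pydantic import BaseModel, ConfigDict, PositiveFloat, PositiveInt, ValidationError
from pydantic import NonNegativeFloat

from .errors import VolumeValidationError

__all__ = ["AcquisitionMetadata", "OCTVolume", "read_volume", "write_volume"]

_CO_FILE = "co_channel.tif"
_CROSS_FILE = "cross_channel.tif"
_META_FILE = "metadata.json"


class AcquisitionMetadata(BaseModel):
    """Validated acquisition parameters stored alongside every volume."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    ascan_rate_hz: PositiveFloat
    n_ascans_per_bscan: PositiveInt
    n_bscan_locations: PositiveInt
    n_repeats: PositiveInt
    flyback_time_s: NonNegativeFloat
    fov_x_mm: PositiveFloat
    fov_y_mm: PositiveFloat
    axial_pitch_um: PositiveFloat
    center_wavelength_nm: PositiveFloat
    beam_power_mw: NonNegativeFloat
    eye_id: str
    group_label: Literal["transgenic", "wildtype"]
    age_weeks: PositiveFloat

    @property
    def x_pitch_um(self) -> float:
        return 1e3 * self.fov_x_mm / self.n_ascans_per_bscan

    @property
    def y_pitch_um(self) -> float:
        return 1e3 * self.fov_y_mm / self.n_bscan_locations


@dataclass
class OCTVolume:
    """Dual-channel complex OCT volume ``[repeat, y, x, z]`` with metadata."""

    co_channel: np.ndarray
    cross_channel: np.ndarray
    metadata: AcquisitionMetadata

    def __post_init__(self) -> None:
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(self.co_channel.shape)  # type: ignore[return-value]

    @property
    def n_z(self) -> int:
        return self.co_channel.shape[3]

    def validate(self) -> None:
        co, cross = self.co_channel, self.cross_channel
        if co.ndim != 4 or cross.ndim != 4:
            raise VolumeValidationError(
                f"channels must be 4-D [repeat, y, x, z]; got {co.ndim}-D / {cross.ndim}-D"
            )
        if co.shape != cross.shape:
            raise VolumeValidationError(
                f"channel shapes differ: co {co.shape} vs cross {cross.shape}"
            )
        if not (np.iscomplexobj(co) and np.iscomplexobj(cross)):
            raise VolumeValidationError("channels must be complex arrays")
        md = self.metadata
        expected = (md.n_repeats, md.n_bscan_locations, md.n_ascans_per_bscan)
        if co.shape[:3] != expected:
            for axis, (got, want, field) in enumerate(
                zip(
                    co.shape[:3],
                    expected,
                    ("n_repeats", "n_bscan_locations", "n_ascans_per_bscan"),
                )
            ):
                if got != want:
                    raise VolumeValidationError(
                        f"axis {axis} has size {got} but metadata field "
                        f"{field} = {want}"
                    )
        if not np.isfinite(co).all():
            raise VolumeValidationError("co_channel contains non-finite amplitudes")
        if not np.isfinite(cross).all():
            raise VolumeValidationError("cross_channel contains non-finite amplitudes")

    def amplitude(self, channel: str = "co") -> np.ndarray:
        """|A| of one channel, or the combined quadrature amplitude."""
        if channel == "co":
            return np.abs(self.co_channel)
        if channel == "cross":
            return np.abs(self.cross_channel)
        if channel == "combined":
            return np.sqrt(
                np.abs(self.co_channel) ** 2 + np.abs(self.cross_channel) ** 2
            )
        raise ValueError(f"unknown channel {channel!r}")


def _channel_to_pages(channel: np.ndarray) -> np.ndarray:
    """Stack [repeat, y, x, z] -> pages [(repeat*y)*2, x, z], real/imag interleaved."""
    r, y, x, z = channel.shape
    pages = np.empty((r * y * 2, x, z), dtype=np.float32)
    flat = channel.reshape(r * y, x, z)
    pages[0::2] = flat.real.astype(np.float32)
    pages[1::2] = flat.imag.astype(np.float32)
    return pages


def _pages_to_channel(pages: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    r, y, x = shape
    if pages.ndim == 2:  # single page collapses
        pages = pages[None]
    if pages.shape[0] != r * y * 2:
        raise VolumeValidationError(
            f"stack holds {pages.shape[0] // 2} B-scans but metadata implies {r * y} "
            f"(n_repeats x n_bscan_locations)"
        )
    z = pages.shape[2]
    out = np.empty((r * y, x, z), dtype=np.complex64)
    out.real = pages[0::2]
    out.imag = pages[1::2]
    return out.reshape(r, y, x, z)


def write_volume(volume: OCTVolume, path: str | Path) -> None:
    """Write a volume container (two multi-page TIFFs + JSON sidecar).

    Output bytes are a deterministic function of the volume, so identical
    volumes produce identical files.
    """
    volume.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for fname, channel in ((_CO_FILE, volume.co_channel), (_CROSS_FILE, volume.cross_channel)):
        tifffile.imwrite(
            path / fname,
            _channel_to_pages(channel),
            photometric="minisblack",
        )
    sidecar = json.dumps(volume.metadata.model_dump(), indent=2, sort_keys=True)
    (path / _META_FILE).write_text(sidecar + "\n")


def read_volume(path: str | Path) -> OCTVolume:
    """Read a volume container written by :func:`write_volume`."""
    path = Path(path)
    for fname in (_CO_FILE, _CROSS_FILE, _META_FILE):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing volume file: {path / fname}")
    try:
        metadata = AcquisitionMetadata.model_validate_json(
            (path / _META_FILE).read_text()
        )
    except ValidationError as exc:
        raise VolumeValidationError(f"invalid metadata sidecar: {exc}") from exc
    shape = (metadata.n_repeats, metadata.n_bscan_locations, metadata.n_ascans_per_bscan)
    co = _pages_to_channel(tifffile.imread(path / _CO_FILE), shape)
    cross = _pages_to_channel(tifffile.imread(path / _CROSS_FILE), shape)
    return OCTVolume(co_channel=co, cross_channel=cross, metadata=metadata)
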