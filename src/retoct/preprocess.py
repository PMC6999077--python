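"""Axial motion correction and flattening to the RPE/choroid surface.

The RPE/choroid complex is the strongest depolarizing structure in the
retina, so its depth is detected from the cross-polarized channel, which is
dark everywhere else.  Each A-scan is then rolled by an integer number of
pixels so that the detected surface rests at a common target depth.  Shifts
are integer-only and the complex values are never modified — sub-pixel
interpolation would alter the speckle statistics that the angiography stage
depends on.

A dataset whose flattening fails (poor SNR: too many A-scans below the noise
floor) raises :class:`~retoct.errors.ExclusionError` so the caller can record
the exclusion; it never silently degrades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .config import PreprocessConfig
from .errors import ExclusionError, NoSignalError, VolumeValidationError
from .io import OCTVolume

__all__ = [
    "FlattenResult",
    "estimate_axial_offsets",
    "detect_rpe_crosspol",
    "flatten_volume",
]


@dataclass
class FlattenResult:
    """Flattened volume plus the bookkeeping needed to audit or undo it."""

    volume: OCTVolume
    shift_px: np.ndarray          # (y, x) integer shift applied to each A-scan
    rpe_depth_px: np.ndarray      # detected RPE depth map used for flattening
    bscan_offsets_px: np.ndarray  # per-B-scan axial motion estimate
    quality: np.ndarray           # per-B-scan boolean quality flag
    target_px: int


def estimate_axial_offsets(volume: OCTVolume) -> np.ndarray:
    """Per-B-scan axial offset (pixels) relative to the first B-scan.

    The depth-wise mean intensity profile of each B-scan (averaged over
    repeats and the fast axis) is cross-correlated with its predecessor; the
    lag maximizing the correlation is accumulated along the slow axis.
    """
    if volume.shape[1] < 2:
        raise VolumeValidationError("need at least 2 B-scans to estimate motion")
    inten = (volume.amplitude("combined") ** 2).mean(axis=(0, 2))  # (y, z)
    if np.allclose(inten, 0.0):
        raise NoSignalError("no signal: volume intensity is zero")
    # remove the DC component so the correlation peak tracks structure
    prof = inten - inten.mean(axis=1, keepdims=True)
    ny, nz = prof.shape
    offsets = np.zeros(ny, dtype=int)
    for y in range(1, ny):
        corr = signal.correlate(prof[y], prof[y - 1], mode="full")
        lag = int(np.argmax(corr)) - (nz - 1)
        offsets[y] = offsets[y - 1] + lag
    return offsets


def detect_rpe_crosspol(
    volume: OCTVolume, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Depth of the RPE/choroid complex from the cross-polarized channel.

    Per A-scan: depth of the maximum of the axially boxcar-smoothed
    cross-channel amplitude (averaged over repeats), then a lateral median
    filter.  A-scans whose peak stays below ``snr_factor x noise_floor`` are
    invalid and filled by lateral interpolation; more than
    ``max_invalid_fraction`` invalid A-scans raises :class:`ExclusionError`.

    Returns ``(depth_px, valid_mask)``.
    """
    cfg = config or PreprocessConfig()
    amp = np.abs(volume.cross_channel).mean(axis=0)  # (y, x, z)
    smoothed = ndimage.uniform_filter1d(amp, size=cfg.rpe_boxcar_px, axis=2, mode="nearest")
    depth = np.argmax(smoothed, axis=2).astype(float)
    peak = smoothed.max(axis=2)
    valid = peak > cfg.snr_factor * cfg.noise_floor
    frac_invalid = 1.0 - valid.mean()
    if frac_invalid > cfg.max_invalid_fraction:
        raise ExclusionError(
            f"RPE detection failed: {frac_invalid:.0%} of A-scans below the noise floor"
        )
    if not valid.all():
        depth = _fill_invalid(depth, valid)
    depth = ndimage.median_filter(
        depth, size=(cfg.rpe_median_y_px, cfg.rpe_median_x_px), mode="nearest"
    )
    return depth, valid


def _fill_invalid(depth: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Nearest-neighbour lateral interpolation of invalid map pixels."""
    idx = ndimage.distance_transform_edt(
        ~valid, return_distances=False, return_indices=True
    )
    return depth[tuple(idx)]


def flatten_volume(
    volume: OCTVolume,
    rpe_depth_px: np.ndarray,
    bscan_offsets_px: np.ndarray | None = None,
    config: PreprocessConfig | None = None,
) -> FlattenResult:
    """Roll every A-scan so the detected RPE sits at a common target depth.

    The target is ``flatten_target_fraction`` of the z extent.  Both channels
    and all repeats are shifted identically by integer pixels with zero
    padding, so complex differences between repeats are untouched outside the
    padded margin.
    """
    cfg = config or PreprocessConfig()
    nr, ny, nx, nz = volume.shape
    if rpe_depth_px.shape != (ny, nx):
        raise VolumeValidationError(
            f"rpe map shape {rpe_depth_px.shape} does not match volume ({ny}, {nx})"
        )
    target = int(round(cfg.flatten_target_fraction * nz))
    shift = np.round(target - rpe_depth_px).astype(int)
    if (np.abs(shift) >= nz).any():
        raise VolumeValidationError("flattening shift exceeds the volume z extent")

    co = np.zeros_like(volume.co_channel)
    cross = np.zeros_like(volume.cross_channel)
    zz = np.arange(nz)
    for y in range(ny):
        src = zz[None, :] - shift[y][:, None]          # (x, z) source index
        ok = (src >= 0) & (src < nz)
        src_c = np.clip(src, 0, nz - 1)
        for arr_out, arr_in in ((co, volume.co_channel), (cross, volume.cross_channel)):
            block = np.take_along_axis(arr_in[:, y], src_c[None], axis=2)
            block[:, ~ok] = 0
            arr_out[:, y] = block

    flat = OCTVolume(co_channel=co, cross_channel=cross, metadata=volume.metadata)
    offsets = (
        bscan_offsets_px
        if bscan_offsets_px is not None
        else np.zeros(ny, dtype=int)
    )
    # quality: a B-scan is trustworthy if its shifts are consistent (low spread)
    spread = shift.max(axis=1) - shift.min(axis=1)
    quality = spread <= max(4, int(0.05 * nz))
    return FlattenResult(
        volume=flat,
        shift_px=shift,
        rpe_depth_px=np.asarray(rpe_depth_px, dtype=float),
        bscan_offsets_px=np.asarray(offsets, dtype=int),
        quality=quality,
        target_px=target,
    )
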