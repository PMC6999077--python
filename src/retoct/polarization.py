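"""Phase retardation mapping and depolarizing-deposit screening.

Polarization-preserving tissue returns nearly all backscattered amplitude in
the co-polarized channel, so its retardation delta = arctan(A_cross / A_co)
stays near 0 degrees.  Melanin granules (RPE, choroid, hyaloid remnant near
the ONH) scramble the polarization state, producing retardation values spread
over the full [0, 90] degree range.  Deposits of high retardation *outside*
the expected melanin regions are therefore screened as abnormalities.

Note on channel convention: the default computes arctan(cross/co), which
keeps preserving tissue near 0 degrees; ``literal_channel_convention``
swaps the ratio for comparison purposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PolarizationConfig
from .errors import VolumeValidationError
from .io import OCTVolume
from .layers import LayerMap

__all__ = [
    "RetardationVolume",
    "DepolarizingDeposit",
    "compute_retardation",
    "build_expected_mask",
    "screen_deposits",
]


@dataclass
class RetardationVolume:
    """Per-voxel retardation in degrees with an SNR validity mask."""

    delta_deg: np.ndarray   # (y, x, z), in [0, 90]
    snr_mask: np.ndarray    # (y, x, z) bool; delta is undefined where False
    axial_pitch_um: float
    x_pitch_um: float
    y_pitch_um: float


@dataclass
class DepolarizingDeposit:
    """One connected high-retardation component outside the expected regions."""

    centroid_um: tuple[float, float, float]  # (x, y, z)
    n_voxels: int
    mean_delta_deg: float
    layer_label: str  # vitreous / inner_retina / outer_retina / posterior


def compute_retardation(
    volume: OCTVolume, config: PolarizationConfig | None = None
) -> RetardationVolume:
    """delta = arctan(A_cross / A_co) in degrees on repeat-averaged amplitudes.

    Voxels whose combined amplitude stays below ``snr_factor x noise_floor``
    are masked (retardation of noise is meaningless).  Zero-amplitude voxels
    map to 0 degrees and are masked.
    """
    cfg = config or PolarizationConfig()
    a_co = np.abs(volume.co_channel).mean(axis=0)
    a_cross = np.abs(volume.cross_channel).mean(axis=0)
    if cfg.literal_channel_convention:
        num, den = a_co, a_cross
    else:
        num, den = a_cross, a_co
    delta = np.degrees(np.arctan2(num, den)).astype(np.float32)
    combined = np.sqrt(a_co**2 + a_cross**2)
    snr_mask = combined > cfg.snr_factor * cfg.noise_floor
    md = volume.metadata
    return RetardationVolume(
        delta_deg=delta,
        snr_mask=snr_mask,
        axial_pitch_um=md.axial_pitch_um,
        x_pitch_um=md.x_pitch_um,
        y_pitch_um=md.y_pitch_um,
    )


def build_expected_mask(
    layer_map: LayerMap,
    n_z: int,
    onh_center_um: tuple[float, float] | None = None,
    onh_radius_um: float = 0.0,
    config: PolarizationConfig | None = None,
) -> np.ndarray:
    """Voxel mask of regions where depolarization is anatomically expected.

    Union of the RPE/choroid slab (z >= posterior RPE - rpe_margin_um) and a
    cylinder around the ONH center (radius + onh_margin_um), derived
    deterministically from the layer map and annulus geometry.
    """
    cfg = config or PolarizationConfig()
    ny, nx = layer_map.rpe_px.shape
    zz = np.arange(n_z)[None, None, :]
    rpe_start = np.round(
        layer_map.rpe_px - cfg.rpe_margin_um / layer_map.axial_pitch_um
    )
    mask = zz >= rpe_start[:, :, None]
    if onh_center_um is not None:
        cx, cy = onh_center_um
        xs = (np.arange(nx) + 0.5) * layer_map.x_pitch_um
        ys = (np.arange(ny) + 0.5) * layer_map.y_pitch_um
        lateral = np.hypot(xs[None, :] - cx, ys[:, None] - cy) < (
            onh_radius_um + cfg.onh_margin_um
        )
        mask |= lateral[:, :, None]
    return mask


def _layer_label(z_px: float, iy: int, ix: int, layer_map: LayerMap) -> str:
    if z_px < layer_map.ilm_px[iy, ix]:
        return "vitreous"
    if z_px < layer_map.opl_px[iy, ix]:
        return "inner_retina"
    if z_px < layer_map.rpe_px[iy, ix]:
        return "outer_retina"
    return "posterior"


def screen_deposits(
    retardation: RetardationVolume,
    expected_mask: np.ndarray,
    layer_map: LayerMap,
    config: PolarizationConfig | None = None,
) -> list[DepolarizingDeposit]:
    """Automated screen for abnormal depolarizing deposits.

    Candidate voxels are SNR-valid, exceed the retardation threshold, and lie
    outside the expected melanin mask; 26-connected components of at least
    ``min_component_voxels`` voxels are reported with centroid, size, mean
    retardation, and the retinal compartment of the centroid.
    """
    cfg = config or PolarizationConfig()
    if expected_mask.shape != retardation.delta_deg.shape:
        raise VolumeValidationError("expected mask shape does not match volume")
    cand = (
        retardation.snr_mask
        & (retardation.delta_deg > cfg.delta_threshold_deg)
        & ~expected_mask
    )
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(cand, structure=structure)
    deposits: list[DepolarizingDeposit] = []
    if n == 0:
        return deposits
    # a component adjacent to the expected mask is attached to the RPE/choroid
    # complex (or the ONH remnant), not an ectopic deposit
    border = ndimage.binary_dilation(expected_mask, structure=structure) & ~expected_mask
    attached = set(np.unique(labels[border])) - {0}
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(cand, labels, index=np.arange(1, n + 1))
    means = ndimage.mean(retardation.delta_deg, labels, index=np.arange(1, n + 1))
    for k in range(n):
        if sizes[k] < cfg.min_component_voxels or (k + 1) in attached:
            continue
        cy, cx, cz = centroids[k]
        deposits.append(
            DepolarizingDeposit(
                centroid_um=(
                    (cx + 0.5) * retardation.x_pitch_um,
                    (cy + 0.5) * retardation.y_pitch_um,
                    (cz + 0.5) * retardation.axial_pitch_um,
                ),
                n_voxels=int(sizes[k]),
                mean_delta_deg=float(means[k]),
                layer_label=_layer_label(cz, int(round(cy)), int(round(cx)), layer_map),
            )
        )
    return deposits
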