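"""Synthetic dual-channel PS-OCT phantoms, cohort tables, and histology images.

The phantom emulates exactly the statistical structure the downstream stages
rely on, with complete ground truth:

* a layered retina (vitreous / inner retina / bright OPL band / ONL /
  melanin-rich RPE band / choroid) with smooth spatial undulation, fully
  developed speckle (independent circular complex Gaussian per voxel), and an
  additive complex noise floor;
* repeated B-scans at each slow-axis location in which static tissue is
  speckle-correlated across repeats while voxels inside flow (vessel) regions
  are redrawn independently with a configurable decorrelation fraction —
  the contrast mechanism of complex-difference angiography;
* a polarization split: polarization-preserving tissue keeps >=99% of its
  amplitude in the co-polarized channel, while melanin-containing voxels
  (RPE band, choroid, hyaloid remnant, ectopic deposits) scramble the state,
  drawing a per-voxel retardation angle uniform on [0, 90] degrees;
* hyper-reflective foci as spherical reflectivity multipliers in the outer
  retina;
* per-B-scan axial motion (integer random walk) and per-repeat global phase
  offsets, the artifacts the preprocessing and bulk-phase stages remove;
* an optic nerve head rendered as a layerless depression with a depolarizing
  remnant column, so annulus and exclusion-mask logic is exercised.

Ground truth (boundary maps, vessel masks, HRF and deposit voxel masks,
applied motion) is returned alongside the volume.  A cohort-level
thickness-vs-age generator and a brightfield plaque-image generator feed the
statistics and histomorphometry stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage

from .errors import VolumeValidationError
from .io import AcquisitionMetadata, OCTVolume

__all__ = [
    "LayerModel",
    "ONHModel",
    "VesselSpec",
    "MelaninDepositSpec",
    "HRFSpec",
    "MotionModel",
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "GroupCohort",
    "CohortConfig",
    "generate_cohort",
    "generate_histology_image",
    "THICKNESS_METRICS",
]

#: Mean retardation-weighted amplitude factors used by the noise-free forward
#: model of the cross-polarized channel: E[sin(delta)] for delta ~ U(0, 90deg)
#: is 2/pi; preserving tissue contributes a small residual.
_MELANIN_SIN = 2.0 / math.pi
_PRESERVING_SIN = 0.03


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayerModel(_Strict):
    """Axial layer architecture in micrometers (depths from the volume top)."""

    ilm_um: float = 160.0
    posterior_opl_um: float = 290.0
    posterior_rpe_um: float = 384.0
    opl_band_um: float = 12.0
    rpe_band_um: float = 4.0
    reflectivity_inner: float = 0.5
    reflectivity_opl: float = 0.9
    reflectivity_onl: float = 0.3
    reflectivity_rpe: float = 1.2
    reflectivity_choroid: float = 0.5
    choroid_attenuation_um: float = 40.0
    undulation_amp_um: float = 6.0
    undulation_period_um: float = 500.0

    @model_validator(mode="after")
    def _ordered(self) -> "LayerModel":
        if not (0 < self.ilm_um < self.posterior_opl_um < self.posterior_rpe_um):
            raise ValueError("layer boundaries must be strictly increasing in depth")
        if self.opl_band_um <= 0 or self.rpe_band_um <= 0:
            raise ValueError("band thicknesses must be positive")
        return self


class ONHModel(_Strict):
    """Optic nerve head: layerless disc with a depolarizing remnant column."""

    center_x_um: float = 500.0
    center_y_um: float = 500.0
    radius_um: float = 100.0
    remnant_radius_um: float = 30.0
    remnant_reflectivity: float = 0.4


class VesselSpec(_Strict):
    """Straight vessel segment in one plexus, en-face endpoints in um."""

    plexus: Literal["SVP", "DCP"]
    x0_um: float
    y0_um: float
    x1_um: float
    y1_um: float
    radius_um: float = Field(gt=0.0)
    decorrelation: float = Field(ge=0.0, le=1.0)
    reflectivity: float = Field(0.5, gt=0.0, description="blood backscatter amplitude, independent of the host layer")


class MelaninDepositSpec(_Strict):
    """Ectopic depolarizing deposit: a sphere at a fractional retinal depth."""

    x_um: float
    y_um: float
    depth_frac: float = Field(ge=0.0, le=1.0, description="0 = ILM, 1 = posterior RPE")
    radius_um: float = Field(gt=0.0)
    reflectivity: float = 0.6


class HRFSpec(_Strict):
    """Hyper-reflective focus: spherical reflectivity multiplier, outer retina."""

    x_um: float
    y_um: float
    depth_frac: float = Field(ge=0.0, le=1.0, description="0 = posterior OPL, 1 = posterior RPE")
    radius_um: float = Field(gt=0.0)
    amplitude_factor: float = Field(4.0, gt=1.0)


class MotionModel(_Strict):
    """Axial bulk motion: integer random-walk shift per B-scan location."""

    axial_walk_sigma_px: float = Field(0.0, ge=0.0)
    repeat_phase: bool = Field(True, description="apply a random global phase per repeat")


class PhantomConfig(_Strict):
    """Full phantom description; :meth:`default` builds a standard retina."""

    n_repeats: int = Field(5, ge=1)
    n_y: int = Field(100, ge=4)
    n_x: int = Field(128, ge=4)
    n_z: int = Field(256, ge=16)
    fov_x_mm: float = Field(1.0, gt=0.0)
    fov_y_mm: float = Field(1.0, gt=0.0)
    axial_pitch_um: float = Field(2.0, gt=0.0)
    layers: LayerModel = Field(default_factory=LayerModel)
    onh: Optional[ONHModel] = None
    vessels: list[VesselSpec] = Field(default_factory=list)
    melanin_rpe_choroid: bool = True
    melanin_deposits: list[MelaninDepositSpec] = Field(default_factory=list)
    hrf: list[HRFSpec] = Field(default_factory=list)
    motion: MotionModel = Field(default_factory=MotionModel)
    noise_floor: float = Field(0.05, ge=0.0)
    speckle: bool = True
    preserving_delta_sigma_deg: float = Field(2.0, ge=0.0)
    preserving_delta_max_deg: float = Field(5.7, ge=0.0, lt=90.0)
    seed: int = 0
    eye_id: str = "phantom"
    group_label: Literal["transgenic", "wildtype"] = "wildtype"
    age_weeks: float = Field(60.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "PhantomConfig":
        max_um = self.n_z * self.axial_pitch_um
        if self.layers.posterior_rpe_um >= max_um:
            raise ValueError("posterior RPE deeper than the volume z extent")
        return self

    @classmethod
    def default(
        cls,
        shape: tuple[int, int, int, int] = (5, 100, 128, 256),
        *,
        with_onh: bool = True,
        with_vessels: bool = True,
        seed: int = 0,
        **overrides,
    ) -> "PhantomConfig":
        """Standard retina phantom for a given ``(repeat, y, x, z)`` shape.

        Places the posterior RPE at 75% of the z extent (the flattening
        target), a 224-um total retina, and a 130-um inner retina.  Optional
        vessel plexuses span the field of view radially from the center.
        """
        nr, ny, nx, nz = shape
        pitch = overrides.get("axial_pitch_um", 2.0)
        rpe = 0.75 * nz * pitch
        layers = LayerModel(
            ilm_um=rpe - 224.0,
            posterior_opl_um=rpe - 224.0 + 130.0,
            posterior_rpe_um=rpe,
        )
        fov_x = overrides.get("fov_x_mm", 1.0)
        fov_y = overrides.get("fov_y_mm", 1.0)
        cx, cy = 500.0 * fov_x, 500.0 * fov_y
        onh = ONHModel(center_x_um=cx, center_y_um=cy) if with_onh else None
        vessels: list[VesselSpec] = []
        if with_vessels:
            span = 500.0 * min(fov_x, fov_y) - 10.0
            for k, ang in enumerate(np.linspace(0.0, 2 * math.pi, 6, endpoint=False)):
                vessels.append(
                    VesselSpec(
                        plexus="SVP",
                        x0_um=cx, y0_um=cy,
                        x1_um=cx + span * math.cos(ang),
                        y1_um=cy + span * math.sin(ang),
                        radius_um=2.0 * (1e3 * fov_x / nx),
                        decorrelation=1.0,
                    )
                )
            for k, ang in enumerate(np.linspace(0.26, 0.26 + 2 * math.pi, 8, endpoint=False)):
                vessels.append(
                    VesselSpec(
                        plexus="DCP",
                        x0_um=cx, y0_um=cy,
                        x1_um=cx + span * math.cos(ang),
                        y1_um=cy + span * math.sin(ang),
                        radius_um=1.5 * (1e3 * fov_x / nx),
                        decorrelation=1.0,
                    )
                )
        fields = dict(
            n_repeats=nr, n_y=ny, n_x=nx, n_z=nz,
            layers=layers, onh=onh, vessels=vessels, seed=seed,
        )
        fields.update(overrides)
        return cls(**fields)


@dataclass
class PhantomTruth:
    """Ground truth for one generated phantom volume.

    Boundary maps are the *realized* depths in pixels (undulation and motion
    included).  ``rpe_detect_px`` is the depth the cross-polarized RPE
    detector should find: the argmax of the generator's noise-free expected
    cross-amplitude profile after the same 5-px axial boxcar.
    """

    ilm_px: np.ndarray
    opl_px: np.ndarray
    rpe_px: np.ndarray
    valid: np.ndarray
    rpe_detect_px: np.ndarray
    melanin_mask: np.ndarray
    deposit_masks: list[np.ndarray]
    vessel_enface: dict[str, np.ndarray]
    vessel_volume: dict[str, np.ndarray]
    hrf_records: list[dict]
    shifts_px: np.ndarray
    phases_rad: np.ndarray
    onh_center_um: Optional[tuple[float, float]]
    onh_radius_um: float
    config: PhantomConfig

    @property
    def voxel_volume_um3(self) -> float:
        c = self.config
        return (
            (1e3 * c.fov_x_mm / c.n_x)
            * (1e3 * c.fov_y_mm / c.n_y)
            * c.axial_pitch_um
        )


def _segment_distance_enface(
    xs_um: np.ndarray, ys_um: np.ndarray, v: VesselSpec
) -> np.ndarray:
    """Distance (um) from every en-face pixel center to a vessel segment."""
    px = xs_um[None, :] - v.x0_um
    py = ys_um[:, None] - v.y0_um
    dx, dy = v.x1_um - v.x0_um, v.y1_um - v.y0_um
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        return np.hypot(px, py)
    t = np.clip((px * dx + py * dy) / seg2, 0.0, 1.0)
    return np.hypot(px - t * dx, py - t * dy)


def generate_phantom(config: PhantomConfig) -> tuple[OCTVolume, PhantomTruth]:
    """Realize one phantom volume and its ground truth.

    Deterministic for a fixed config (including seed): identical configs give
    bit-identical volumes.
    """
    rng = np.random.default_rng(config.seed)
    nr, ny, nx, nz = config.n_repeats, config.n_y, config.n_x, config.n_z
    zp = config.axial_pitch_um
    xp = 1e3 * config.fov_x_mm / nx
    yp = 1e3 * config.fov_y_mm / ny
    xs_um = (np.arange(nx) + 0.5) * xp
    ys_um = (np.arange(ny) + 0.5) * yp
    L = config.layers

    # -- smooth undulation shared by all boundaries (retina moves as a whole)
    phx, phy = rng.uniform(0, 2 * math.pi, size=2)
    und = L.undulation_amp_um * np.sin(
        2 * math.pi * xs_um[None, :] / L.undulation_period_um + phx
    ) * np.cos(2 * math.pi * ys_um[:, None] / L.undulation_period_um + phy)

    # -- per-B-scan axial motion (integer random walk, shared by all repeats)
    if config.motion.axial_walk_sigma_px > 0:
        steps = np.round(
            rng.normal(0.0, config.motion.axial_walk_sigma_px, size=ny)
        ).astype(int)
        steps[0] = 0
        shifts = np.cumsum(steps)
    else:
        shifts = np.zeros(ny, dtype=int)
    shift_um = (shifts * zp)[:, None]

    ilm_um = L.ilm_um + und + shift_um
    opl_um = L.posterior_opl_um + und + shift_um
    rpe_um = L.posterior_rpe_um + und + shift_um
    ilm_px_map = ilm_um / zp
    opl_px_map = opl_um / zp
    rpe_px_map = rpe_um / zp
    if (rpe_px_map >= nz - 1).any() or (ilm_px_map <= 1).any():
        raise VolumeValidationError("motion/undulation pushed the retina out of the volume")

    # -- reflectivity volume and melanin mask -------------------------------
    zz = np.arange(nz, dtype=np.float32)[None, None, :]

    def at_or_below(boundary_px: np.ndarray) -> np.ndarray:
        return zz >= np.round(boundary_px).astype(np.float32)[:, :, None]

    in_inner = at_or_below(ilm_px_map) & ~at_or_below(opl_px_map - L.opl_band_um / zp)
    in_opl = at_or_below(opl_px_map - L.opl_band_um / zp) & ~at_or_below(opl_px_map)
    in_onl = at_or_below(opl_px_map) & ~at_or_below(rpe_px_map - L.rpe_band_um / zp)
    in_rpe = at_or_below(rpe_px_map - L.rpe_band_um / zp) & ~at_or_below(rpe_px_map)
    in_choroid = at_or_below(rpe_px_map)

    refl = np.zeros((ny, nx, nz), dtype=np.float32)
    refl[in_inner] = L.reflectivity_inner
    refl[in_opl] = L.reflectivity_opl
    refl[in_onl] = L.reflectivity_onl
    refl[in_rpe] = L.reflectivity_rpe
    # choroidal signal decays with depth below the RPE (light attenuation)
    depth_below_um = np.clip(
        (zz - np.round(rpe_px_map).astype(np.float32)[:, :, None]) * zp, 0.0, None
    )
    choroid_refl = (
        L.reflectivity_choroid * np.exp(-depth_below_um / L.choroid_attenuation_um)
    ).astype(np.float32)
    refl[in_choroid] = choroid_refl[in_choroid]

    melanin = np.zeros((ny, nx, nz), dtype=bool)
    if config.melanin_rpe_choroid:
        melanin |= in_rpe | in_choroid

    valid = np.ones((ny, nx), dtype=bool)
    onh_center = None
    onh_radius = 0.0
    if config.onh is not None:
        o = config.onh
        onh_center = (o.center_x_um, o.center_y_um)
        onh_radius = o.radius_um
        d_onh = np.hypot(
            xs_um[None, :] - o.center_x_um, ys_um[:, None] - o.center_y_um
        )
        in_disc = d_onh < o.radius_um
        refl[in_disc] = 0.0
        melanin[in_disc] = False
        valid &= ~in_disc
        in_remnant = d_onh < o.remnant_radius_um
        col = in_remnant[:, :, None] & at_or_below(ilm_px_map) & ~at_or_below(rpe_px_map)
        refl[col] = o.remnant_reflectivity
        melanin[col] = True

    deposit_masks: list[np.ndarray] = []
    for dep in config.melanin_deposits:
        iy = min(ny - 1, max(0, int(dep.y_um / yp)))
        ix = min(nx - 1, max(0, int(dep.x_um / xp)))
        zc_um = ilm_um[iy, ix] + dep.depth_frac * (rpe_um[iy, ix] - ilm_um[iy, ix])
        d2 = (
            ((xs_um[None, :, None] - dep.x_um) / 1.0) ** 2
            + ((ys_um[:, None, None] - dep.y_um) / 1.0) ** 2
            + (((np.arange(nz) + 0.5) * zp)[None, None, :] - zc_um) ** 2
        )
        sphere = d2 <= dep.radius_um**2
        if not sphere.any():
            raise VolumeValidationError("melanin deposit smaller than one voxel")
        refl[sphere] = np.maximum(refl[sphere], dep.reflectivity)
        melanin |= sphere
        deposit_masks.append(sphere)

    hrf_records: list[dict] = []
    voxvol = xp * yp * zp
    for h in config.hrf:
        iy = min(ny - 1, max(0, int(h.y_um / yp)))
        ix = min(nx - 1, max(0, int(h.x_um / xp)))
        # depth_frac spans the feasible center range, so the sphere always
        # fits inside the outer retina (posterior OPL .. anterior RPE)
        lo = opl_um[iy, ix] + h.radius_um
        hi = max(lo, rpe_um[iy, ix] - L.rpe_band_um - h.radius_um)
        zc_um = lo + h.depth_frac * (hi - lo)
        d2 = (
            (xs_um[None, :, None] - h.x_um) ** 2
            + (ys_um[:, None, None] - h.y_um) ** 2
            + (((np.arange(nz) + 0.5) * zp)[None, None, :] - zc_um) ** 2
        )
        sphere = d2 <= h.radius_um**2
        if not sphere.any():
            raise VolumeValidationError("HRF smaller than one voxel")
        refl[sphere] *= h.amplitude_factor
        hrf_records.append(
            {
                "center_um": (h.x_um, h.y_um, zc_um),
                "radius_um": h.radius_um,
                "mask": sphere,
                "n_voxels": int(sphere.sum()),
                "volume_um3": float(sphere.sum()) * voxvol,
                "amplitude_factor": h.amplitude_factor,
                "depth_frac": h.depth_frac,
            }
        )

    # -- vessels -------------------------------------------------------------
    decor = np.zeros((ny, nx, nz), dtype=np.float32)
    vessel_enface = {
        "SVP": np.zeros((ny, nx), dtype=bool),
        "DCP": np.zeros((ny, nx), dtype=bool),
    }
    vessel_volume = {
        "SVP": np.zeros((ny, nx, nz), dtype=bool),
        "DCP": np.zeros((ny, nx, nz), dtype=bool),
    }
    z_um_grid = ((np.arange(nz) + 0.5) * zp)[None, None, :]
    for v in config.vessels:
        dist = _segment_distance_enface(xs_um, ys_um, v)
        lateral = dist <= v.radius_um
        # tube clipped to its plexus slab so vessels live exactly where the
        # en-face projections look for them (SVP: 20 um below the ILM,
        # DCP: 15 um above the posterior OPL)
        if v.plexus == "SVP":
            zc = ilm_um + min(10.0, v.radius_um)
            slab_lo, slab_hi = ilm_um, ilm_um + 20.0
        else:
            zc = opl_um - min(7.5, v.radius_um)
            slab_lo, slab_hi = opl_um - 15.0, opl_um
        axial = (
            (np.abs(z_um_grid - zc[:, :, None]) <= v.radius_um)
            & (z_um_grid >= slab_lo[:, :, None])
            & (z_um_grid <= slab_hi[:, :, None])
        )
        tube = lateral[:, :, None] & axial
        vessel_enface[v.plexus] |= lateral
        vessel_volume[v.plexus] |= tube
        refl[tube] = v.reflectivity
        np.maximum(decor, np.where(tube, np.float32(v.decorrelation), np.float32(0.0)), out=decor)
    has_flow = decor.max() > 0

    # -- retardation angles ---------------------------------------------------
    delta_deg = np.abs(
        rng.normal(0.0, config.preserving_delta_sigma_deg, size=(ny, nx, nz))
    )
    np.clip(delta_deg, 0.0, config.preserving_delta_max_deg, out=delta_deg)
    n_mel = int(melanin.sum())
    if n_mel:
        delta_deg[melanin] = rng.uniform(0.0, 90.0, size=n_mel)
    delta = np.deg2rad(delta_deg).astype(np.float32)
    cosd = np.cos(delta)
    sind = np.sin(delta)
    del delta, delta_deg

    # -- speckle fields and channel split ------------------------------------
    def complex_normal(shape: tuple[int, ...]) -> np.ndarray:
        re = rng.standard_normal(shape, dtype=np.float32)
        im = rng.standard_normal(shape, dtype=np.float32)
        return ((re + 1j * im) / np.sqrt(np.float32(2.0))).astype(np.complex64)

    if config.motion.repeat_phase:
        phases = rng.uniform(0.0, 2 * math.pi, size=nr)
        phases[0] = 0.0
    else:
        phases = np.zeros(nr)

    co = np.empty((nr, ny, nx, nz), dtype=np.complex64)
    cross = np.empty((nr, ny, nx, nz), dtype=np.complex64)
    g0 = complex_normal((ny, nx, nz)) if config.speckle else np.ones((ny, nx, nz), np.complex64)
    # flow model: autoregressive speckle renewal inside vessels,
    # g_{r+1} = sqrt(1-p) g_r + sqrt(p) fresh.  The chain is stationary
    # (every repeat keeps circular-Gaussian speckle), every consecutive pair
    # decorrelates by the same amount, and the angiogram amplitude grows
    # monotonically with the renewal fraction p.
    keep = np.sqrt(1.0 - decor)
    renew = np.sqrt(decor)
    g_prev = g0
    for r in range(nr):
        if config.speckle and has_flow and r > 0:
            g = keep * g_prev + renew * complex_normal((ny, nx, nz))
        else:
            g = g_prev
        fld = refl * g
        co_r = fld * cosd
        cross_r = fld * sind
        if config.noise_floor > 0:
            co_r = co_r + config.noise_floor * complex_normal((ny, nx, nz))
            cross_r = cross_r + config.noise_floor * complex_normal((ny, nx, nz))
        if phases[r] != 0.0:
            rot = np.complex64(np.exp(1j * phases[r]))
            co_r = co_r * rot
            cross_r = cross_r * rot
        co[r] = co_r
        cross[r] = cross_r
        g_prev = g

    metadata = AcquisitionMetadata(
        ascan_rate_hz=83_000.0,
        n_ascans_per_bscan=nx,
        n_bscan_locations=ny,
        n_repeats=nr,
        flyback_time_s=1.5e-3,
        fov_x_mm=config.fov_x_mm,
        fov_y_mm=config.fov_y_mm,
        axial_pitch_um=zp,
        center_wavelength_nm=840.0,
        beam_power_mw=2.85,
        eye_id=config.eye_id,
        group_label=config.group_label,
        age_weeks=config.age_weeks,
    )
    volume = OCTVolume(co_channel=co, cross_channel=cross, metadata=metadata)

    # -- forward-model expected cross-amplitude profile -> detector truth ----
    exp_cross = refl * np.where(melanin, np.float32(_MELANIN_SIN), np.float32(_PRESERVING_SIN))
    smoothed = ndimage.uniform_filter1d(exp_cross, size=5, axis=2, mode="nearest")
    rpe_detect = np.argmax(smoothed, axis=2).astype(np.float32)

    truth = PhantomTruth(
        ilm_px=np.round(ilm_px_map).astype(np.float32),
        opl_px=np.round(opl_px_map).astype(np.float32),
        rpe_px=np.round(rpe_px_map).astype(np.float32),
        valid=valid,
        rpe_detect_px=rpe_detect,
        melanin_mask=melanin,
        deposit_masks=deposit_masks,
        vessel_enface=vessel_enface,
        vessel_volume=vessel_volume,
        hrf_records=hrf_records,
        shifts_px=shifts,
        phases_rad=np.asarray(phases),
        onh_center_um=onh_center,
        onh_radius_um=onh_radius,
        config=config,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Cohort-level thickness model
# ---------------------------------------------------------------------------

#: The nine thickness metrics: compartment x annulus region.
THICKNESS_METRICS = [
    f"{comp}_{region}"
    for comp in ("total", "inner", "outer")
    for region in ("whole", "superior", "inferior")
]


class GroupCohort(_Strict):
    """Linear thickness-vs-age model for one genotype group."""

    n_eyes: int = Field(ge=2)
    age_min_weeks: float = Field(gt=0.0)
    age_max_weeks: float
    baseline_um: float = Field(gt=0.0, description="total thickness extrapolated to age 0")
    slope_um_per_week: float = Field(description="thinning rate; positive = thinning")
    sigma_um: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _ages(self) -> "GroupCohort":
        if self.age_max_weeks < self.age_min_weeks:
            raise ValueError("age_max_weeks < age_min_weeks")
        return self


class CohortConfig(_Strict):
    """Two-group cohort; defaults mirror the study conditions (44 transgenic /
    28 wild-type eyes, ages 45-104 weeks, total thinning 0.37 vs 0.26 um/week)."""

    transgenic: GroupCohort = Field(
        default_factory=lambda: GroupCohort(
            n_eyes=44, age_min_weeks=45, age_max_weeks=104,
            baseline_um=250.0, slope_um_per_week=0.37, sigma_um=5.0,
        )
    )
    wildtype: GroupCohort = Field(
        default_factory=lambda: GroupCohort(
            n_eyes=28, age_min_weeks=45, age_max_weeks=104,
            baseline_um=245.0, slope_um_per_week=0.26, sigma_um=5.0,
        )
    )
    inner_fraction: float = Field(0.58, gt=0.0, lt=1.0)
    seed: int = 0


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """One row per eye with all nine thickness metrics.

    Within each annulus region the total thickness is baseline − slope·age
    plus Gaussian noise; inner = fraction × total and outer = total − inner,
    so inner + outer = total holds exactly by construction.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for group in ("transgenic", "wildtype"):
        g: GroupCohort = getattr(config, group)
        ages = rng.uniform(g.age_min_weeks, g.age_max_weeks, size=g.n_eyes)
        for i, age in enumerate(ages):
            row: dict = {
                "eye_id": f"{group[:2]}_{i:03d}",
                "group": group,
                "age_weeks": float(age),
            }
            for region in ("whole", "superior", "inferior"):
                total = g.baseline_um - g.slope_um_per_week * age
                if g.sigma_um > 0:
                    total += rng.normal(0.0, g.sigma_um)
                inner = config.inner_fraction * total
                row[f"total_{region}"] = total
                row[f"inner_{region}"] = inner
                row[f"outer_{region}"] = total - inner
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Brightfield plaque-image phantom
# ---------------------------------------------------------------------------

_TISSUE_RGB = np.array([0.91, 0.71, 0.77])  # eosin-pink background
_PLAQUE_RGB = np.array([0.48, 0.29, 0.12])  # DAB brown


def generate_histology_image(
    n_plaques: int,
    field_area_mm2: float,
    seed: int,
    pixel_size_um: float = 2.0,
    radius_range_um: tuple[float, float] = (8.0, 25.0),
) -> tuple[np.ndarray, int]:
    """Synthetic brightfield immunostain: brown disks on pink tissue.

    Plaques are non-overlapping; raises if the field cannot host them.
    Returns ``(rgb uint8 image, truth count)``.
    """
    if n_plaques < 0:
        raise VolumeValidationError("n_plaques must be >= 0")
    if field_area_mm2 <= 0:
        raise VolumeValidationError("field_area_mm2 must be positive")
    rng = np.random.default_rng(seed)
    side_um = 1e3 * math.sqrt(field_area_mm2)
    n_px = int(round(side_um / pixel_size_um))
    img = np.clip(
        _TISSUE_RGB[None, None, :] + rng.normal(0.0, 0.02, size=(n_px, n_px, 3)),
        0.0,
        1.0,
    )

    placed: list[tuple[float, float, float]] = []  # (x_um, y_um, r_um)
    attempts = 0
    max_attempts = 300 * max(1, n_plaques)
    while len(placed) < n_plaques:
        attempts += 1
        if attempts > max_attempts:
            raise VolumeValidationError(
                f"could not place {n_plaques} non-overlapping plaques in "
                f"{field_area_mm2} mm^2"
            )
        r = rng.uniform(*radius_range_um)
        margin = r + 2 * pixel_size_um
        x = rng.uniform(margin, side_um - margin)
        y = rng.uniform(margin, side_um - margin)
        if all(
            math.hypot(x - px_, y - py_) > r + pr + 2 * pixel_size_um
            for px_, py_, pr in placed
        ):
            placed.append((x, y, r))

    coords_um = (np.arange(n_px) + 0.5) * pixel_size_um
    for x, y, r in placed:
        brightness = rng.uniform(0.85, 1.15)
        disk = (
            (coords_um[None, :] - x) ** 2 + (coords_um[:, None] - y) ** 2
        ) <= r**2
        img[disk] = np.clip(_PLAQUE_RGB * brightness, 0.0, 1.0)

    return (img * 255).round().astype(np.uint8), n_plaques
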