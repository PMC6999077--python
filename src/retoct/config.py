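"""Pipeline configuration: every tunable of every stage in one validated object.

Each stage module consumes its own sub-config; :class:`PipelineConfig` bundles
them so a whole analysis is reproducible from a single JSON file.  Unknown
keys are rejected to catch typos in config files.
"""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PreprocessConfig",
    "SegmentationConfig",
    "AnnulusConfig",
    "StatsConfig",
    "AngioConfig",
    "PolarizationConfig",
    "HRFConfig",
    "HistologyConfig",
    "PipelineConfig",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PreprocessConfig(_Strict):
    """Axial motion correction and RPE flattening."""

    rpe_boxcar_px: int = Field(5, ge=1, description="axial boxcar on cross-pol amplitude")
    rpe_median_y_px: int = Field(3, ge=1, description="depth-map median across B-scans; kept short because axial motion steps between B-scans are real")
    rpe_median_x_px: int = Field(9, ge=1, description="depth-map median along the fast axis (within one B-scan, motion-free)")
    noise_floor: float = Field(0.05, ge=0.0, description="amplitude noise floor")
    snr_factor: float = Field(3.0, gt=0.0, description="valid if peak > factor x floor")
    max_invalid_fraction: float = Field(0.2, gt=0.0, le=1.0)
    flatten_target_fraction: float = Field(0.75, gt=0.0, lt=1.0, description="RPE rests at this fraction of the z extent")


class SegmentationConfig(_Strict):
    """Reflectivity layer segmentation (ILM / posterior OPL / posterior RPE)."""

    smooth_sigma_y: float = Field(1.0, ge=0.0)
    smooth_sigma_x: float = Field(1.0, ge=0.0)
    smooth_sigma_z: float = Field(1.0, ge=0.0)
    gradient_nsigma: float = Field(4.0, gt=0.0, description="edge threshold: noise mean + n*sigma")
    noise_region_px: int = Field(20, ge=2, description="anterior z rows used as the noise sample")
    boundary_median_px: int = Field(5, ge=1)
    opl_rpe_margin_px: int = Field(10, ge=1, description="gap excluded anterior to the RPE peak when locating the OPL edge")
    max_invalid_fraction: float = Field(0.3, gt=0.0, le=1.0)


class AnnulusConfig(_Strict):
    """Peripapillary measurement annulus around the optic nerve head."""

    inner_diameter_um: float = Field(500.0, ge=0.0)
    outer_diameter_um: float = Field(900.0, gt=0.0)
    orientation_deg: float = Field(0.0, description="transverse split line; 0 = fast axis")


class StatsConfig(_Strict):
    """Age-trend pretest and group-comparison settings."""

    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    bonferroni: bool = Field(False, description="correct across the 9 thickness metrics")


class AngioConfig(_Strict):
    """OCTA computation, binarization, and vessel quantification."""

    exclusion_threshold: float = Field(0.6, gt=0.0, description="mean normalized complex difference above which a repeat is dropped")
    svp_slab_um: float = Field(20.0, gt=0.0, description="slab depth below the ILM")
    dcp_slab_um: float = Field(15.0, gt=0.0, description="slab depth above the posterior OPL")
    clahe_clip_limit: float = Field(0.01, gt=0.0)
    clahe_tiles: int = Field(8, ge=1, description="tile grid per image side")
    morph_radius_px: int = Field(1, ge=1, description="disk radius for opening/closing")
    mean_filter_px: int = Field(5, ge=1, description="square averaging filter on the skeleton")


class PolarizationConfig(_Strict):
    """Phase retardation and depolarizing-deposit screening."""

    literal_channel_convention: bool = Field(
        False,
        description="if True use arctan(co/cross); default arctan(cross/co) keeps preserving tissue near 0 degrees",
    )
    noise_floor: float = Field(0.05, ge=0.0)
    snr_factor: float = Field(3.0, gt=0.0)
    delta_threshold_deg: float = Field(30.0, gt=0.0, lt=90.0)
    min_component_voxels: int = Field(27, ge=1)
    rpe_margin_um: float = Field(5.0, ge=0.0, description="expected-mask extension anterior to the posterior RPE")
    onh_margin_um: float = Field(50.0, ge=0.0)


class HRFConfig(_Strict):
    """Hyper-reflective focus detection in the outer retina."""

    threshold_db: float = Field(6.0, gt=0.0, description="excess over the per-depth background median")
    smooth_sigma: float = Field(1.0, ge=0.0, description="3-D Gaussian on the log intensity; static-tissue speckle is frozen across repeats, so spatial averaging is the only smoothing available")
    delineation_fraction: float = Field(0.75, gt=0.0, le=1.0, description="hysteresis contour for volume measurement, as a fraction of threshold_db; compensates the smoothing erosion of the detection contour")
    min_voxels: int = Field(8, ge=1)
    max_voxels: int = Field(4000, ge=1)
    rpe_margin_um: float = Field(4.0, ge=0.0, description="components reaching this close to the posterior RPE are excluded")


class HistologyConfig(_Strict):
    """Brown-deposit (DAB) segmentation on brightfield RGB images."""

    hue_min_deg: float = Field(10.0, ge=0.0, le=360.0)
    hue_max_deg: float = Field(40.0, ge=0.0, le=360.0)
    saturation_min: float = Field(0.2, ge=0.0, le=1.0)
    value_max: float = Field(0.9, ge=0.0, le=1.0)
    min_area_um2: float = Field(20.0, gt=0.0)


class PipelineConfig(_Strict):
    """All stage configs plus the global random seed."""

    seed: int = 0
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    annulus: AnnulusConfig = Field(default_factory=AnnulusConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    angio: AngioConfig = Field(default_factory=AngioConfig)
    polarization: PolarizationConfig = Field(default_factory=PolarizationConfig)
    hrf: HRFConfig = Field(default_factory=HRFConfig)
    histology: HistologyConfig = Field(default_factory=HistologyConfig)

    def to_json(self, path: str | Path | None = None) -> str:
        text = self.model_dump_json(indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())
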