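"""Retinal layer segmentation, peripapillary annulus, thickness morphometry,
and the age-trend pretest -> ANCOVA/ANOVA group comparison.

Three boundaries are segmented on the repeat-averaged log-intensity of the
co-polarized channel of a flattened volume:

* **ILM** — the first axial rising edge above a noise-adaptive gradient
  threshold (vitreous -> inner retina);
* **posterior OPL** — the most posterior falling edge of the hyper-reflective
  OPL band, searched between the ILM and the RPE peak; it splits the retina
  into inner and outer compartments;
* **posterior RPE** — the last falling edge at or below the RPE reflectivity
  peak (RPE band -> choroid).

Total retina = ILM .. posterior RPE; inner + outer = total by construction.

Mean thicknesses are evaluated inside an annulus centered on the optic nerve
head (default diameters 500/900 um) and in its superior and inferior halves,
giving nine metrics per eye.  For each metric, a least-squares regression
pretest asks whether thickness depends on age within each group; if both
groups are age-dependent the groups are compared by ANCOVA (age x group
interaction — a difference in the thinning trend), otherwise by one-way
ANOVA on the group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import ndimage, stats
from statsmodels.stats.anova import anova_lm

from .config import AnnulusConfig, SegmentationConfig, StatsConfig
from .errors import ExclusionError, VolumeValidationError
from .io import OCTVolume
from .phantom import THICKNESS_METRICS

__all__ = [
    "LayerMap",
    "AnnulusMask",
    "ThicknessRecord",
    "GroupComparison",
    "segment_layers",
    "build_annulus",
    "compute_thickness",
    "fit_age_pretest",
    "compare_groups",
    "compare_all_metrics",
]


@dataclass
class LayerMap:
    """Per-(y, x) boundary depths in pixels, with physical pitches attached."""

    ilm_px: np.ndarray
    opl_px: np.ndarray
    rpe_px: np.ndarray
    valid: np.ndarray
    axial_pitch_um: float
    x_pitch_um: float
    y_pitch_um: float

    def __post_init__(self) -> None:
        bad = (
            (self.ilm_px >= self.opl_px) | (self.opl_px >= self.rpe_px)
        ) & self.valid
        if bad.any():
            raise VolumeValidationError(
                "boundary ordering ILM < OPL < RPE violated on valid pixels"
            )

    @property
    def total_um(self) -> np.ndarray:
        return (self.rpe_px - self.ilm_px) * self.axial_pitch_um

    @property
    def inner_um(self) -> np.ndarray:
        return (self.opl_px - self.ilm_px) * self.axial_pitch_um

    @property
    def outer_um(self) -> np.ndarray:
        return (self.rpe_px - self.opl_px) * self.axial_pitch_um


@dataclass
class AnnulusMask:
    """En-face ring mask around the ONH split into superior/inferior halves."""

    annulus: np.ndarray
    superior: np.ndarray
    inferior: np.ndarray
    center_um: tuple[float, float]
    inner_diameter_um: float
    outer_diameter_um: float
    orientation_deg: float

    def region(self, name: str) -> np.ndarray:
        return {"whole": self.annulus, "superior": self.superior, "inferior": self.inferior}[name]


@dataclass
class ThicknessRecord:
    """The nine per-eye thickness metrics (um)."""

    eye_id: str
    group: str
    age_weeks: float
    metrics: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"eye_id": self.eye_id, "group": self.group, "age_weeks": self.age_weeks}
        row.update(self.metrics)
        return row


@dataclass
class GroupComparison:
    """Outcome of the pretest -> ANCOVA/ANOVA procedure for one metric."""

    metric: str
    pretest_p: dict[str, float]
    slopes_um_per_week: dict[str, float]  # signed OLS slopes
    chosen_test: str                      # "ANCOVA" or "ANOVA"
    p_value: float
    p_adjusted_means: float | None = None  # secondary ANCOVA group effect


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_layers(
    volume: OCTVolume,
    config: SegmentationConfig | None = None,
    rpe_peak_px: np.ndarray | None = None,
) -> LayerMap:
    """Segment ILM / posterior OPL / posterior RPE on a flattened volume.

    Edges are found on the axial gradient of the (optionally smoothed)
    repeat-averaged log intensity; the threshold adapts to the gradient
    statistics of the anterior noise region (mean + n*sigma).  The RPE peak
    anchoring the posterior searches is taken from the cross-polarized
    channel (the same depolarizing landmark used for flattening) unless a
    map is supplied.  Boundaries are median-filtered laterally; pixels
    violating monotonicity or lacking edges are flagged invalid and filled
    by nearest-neighbour interpolation.
    """
    cfg = config or SegmentationConfig()
    if rpe_peak_px is None:
        from .preprocess import detect_rpe_crosspol

        rpe_peak_px, _ = detect_rpe_crosspol(volume)
    amp = np.abs(volume.co_channel).mean(axis=0)
    # floor amplitudes at the noise level so zero-padded voxels from
    # flattening do not inject spurious edges into the log image
    noise_amp = amp[:, :, : cfg.noise_region_px]
    positive = noise_amp[noise_amp > 0]
    floor = float(np.median(positive)) if positive.size else 1e-12
    log_i = 20.0 * np.log10(np.maximum(amp, floor))
    sig = (cfg.smooth_sigma_y, cfg.smooth_sigma_x, cfg.smooth_sigma_z)
    if any(s > 0 for s in sig):
        log_i = ndimage.gaussian_filter(log_i, sigma=sig, mode="nearest")
    grad = np.gradient(log_i, axis=2)

    # Noise-adaptive edge threshold.  Boundary voxels are a small minority,
    # so the median absolute deviation of the axial gradient over the whole
    # volume estimates the speckle gradient noise robustly (the anterior
    # noise region alone underestimates it: its amplitudes are floored).
    # 0.5 dB/px absolute floor: weaker gradients are never real boundaries.
    mad = float(np.median(np.abs(grad - np.median(grad))))
    gthr = max(cfg.gradient_nsigma * 1.4826 * mad, 0.5)

    ny, nx, nz = log_i.shape
    ilm = np.full((ny, nx), np.nan)
    opl = np.full((ny, nx), np.nan)
    rpe = np.full((ny, nx), np.nan)

    rising = grad > gthr
    falling = grad < -gthr

    # Edge localization: each supra-threshold gradient run marks one boundary;
    # the |gradient|-weighted centroid of the run, shifted by the half-pixel
    # offset of the central difference, is unbiased under axial smoothing and
    # exact on a sharp step.
    def _run_centroid(g: np.ndarray, lo: int, hi: int) -> float:
        # restrict to a symmetric window around the steepest voxel so that
        # one-sided shoulders (e.g. choroidal attenuation behind the RPE
        # edge) do not bias the estimate
        k = lo + int(np.argmax(np.abs(g[lo : hi + 1])))
        lo, hi = max(lo, k - 2), min(hi, k + 2)
        w = np.abs(g[lo : hi + 1]) - gthr  # threshold excess de-weights shoulders
        return float((np.arange(lo, hi + 1) * w).sum() / max(w.sum(), 1e-12)) + 0.5

    # ILM: first rising run (vitreous -> inner retina)
    any_rise = rising.any(axis=2)
    peak_z = np.clip(np.round(rpe_peak_px).astype(int), 0, nz - 1)
    for y in range(ny):
        for x in range(nx):
            if not any_rise[y, x]:
                continue
            r_ = rising[y, x]
            f_ = falling[y, x]
            g_ = grad[y, x]
            i0 = int(np.argmax(r_))
            i1 = i0
            while i1 + 1 < nz and r_[i1 + 1]:
                i1 += 1
            ilm[y, x] = _run_centroid(g_, i0, i1)

            # posterior RPE: falling edge at the RPE peak (RPE band -> choroid);
            # the search starts just anterior of the peak so a +-1 px anchor
            # error cannot skip the edge
            pz = int(peak_z[y, x])
            start = max(int(ilm[y, x]) + 2, pz - 3)
            post = np.nonzero(f_[start:])[0]
            if post.size:
                j0 = start + int(post[0])
                j1 = j0
                while j1 + 1 < nz and f_[j1 + 1]:
                    j1 += 1
                rpe[y, x] = _run_centroid(g_, j0, j1)

            # posterior OPL: most posterior *significant* falling run between
            # the ILM and a margin anterior to the RPE peak.  Significance
            # (integrated gradient excess at least half the strongest run's)
            # rejects isolated speckle flickers that would otherwise hijack
            # the most-posterior rule.
            lo = int(ilm[y, x]) + 2
            hi = max(lo, pz - cfg.opl_rpe_margin_px)
            runs = _runs(f_[lo:hi])
            if runs:
                weights = [
                    float((np.abs(g_[lo + a : lo + b + 1]) - gthr).sum())
                    for a, b in runs
                ]
                wmax = max(weights)
                k0, k1 = next(
                    (a, b)
                    for (a, b), w in zip(reversed(runs), reversed(weights))
                    if w >= 0.5 * wmax
                )
                opl[y, x] = _run_centroid(g_, lo + k0, lo + k1)

    found = ~(np.isnan(ilm) | np.isnan(opl) | np.isnan(rpe))
    med = cfg.boundary_median_px
    # median-filter the boundaries as residuals relative to the RPE anchor:
    # anatomy varies smoothly across B-scans while residual per-B-scan motion
    # steps are shared by boundary and anchor, so they cancel in the residual
    anchor = np.asarray(rpe_peak_px, dtype=float)
    filled = []
    for m in (ilm, opl, rpe):
        m2 = _fill_nan(m, found) - anchor
        m2 = ndimage.median_filter(m2, size=med, mode="nearest") + anchor
        filled.append(m2)
    ilm, opl, rpe = filled

    mono = (ilm < opl) & (opl < rpe)
    valid = found & mono
    frac_invalid = 1.0 - valid.mean()
    if frac_invalid > cfg.max_invalid_fraction:
        raise ExclusionError(
            f"layer segmentation failed on {frac_invalid:.0%} of A-scans"
        )
    if not valid.all():
        ilm = _fill_nan(np.where(valid, ilm, np.nan), valid)
        opl = _fill_nan(np.where(valid, opl, np.nan), valid)
        rpe = _fill_nan(np.where(valid, rpe, np.nan), valid)

    md = volume.metadata
    return LayerMap(
        ilm_px=ilm,
        opl_px=opl,
        rpe_px=rpe,
        valid=valid,
        axial_pitch_um=md.axial_pitch_um,
        x_pitch_um=md.x_pitch_um,
        y_pitch_um=md.y_pitch_um,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a 1-D boolean array as (start, stop) inclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0] - 1
    return list(zip(starts.tolist(), stops.tolist()))


def _fill_nan(m: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all():
        return m
    if not valid.any():
        raise ExclusionError("no valid boundary pixels to interpolate from")
    idx = ndimage.distance_transform_edt(~valid, return_distances=False, return_indices=True)
    return m[tuple(idx)]


# ---------------------------------------------------------------------------
# Annulus and thickness
# ---------------------------------------------------------------------------

def build_annulus(
    shape: tuple[int, int],
    onh_center_um: tuple[float, float],
    x_pitch_um: float,
    y_pitch_um: float,
    config: AnnulusConfig | None = None,
) -> AnnulusMask:
    """Ring mask ``inner_r <= r < outer_r`` in physical coordinates.

    ``onh_center_um`` is (x, y).  Pixel centers are at (index + 0.5) * pitch,
    so anisotropic sampling is handled exactly.  The transverse split line
    passes through the center at ``orientation_deg`` (0 = fast axis); the
    superior half is above the line (smaller y).
    """
    cfg = config or AnnulusConfig()
    if cfg.inner_diameter_um > cfg.outer_diameter_um:
        raise VolumeValidationError("inner diameter exceeds outer diameter")
    ny, nx = shape
    cx, cy = onh_center_um
    xs = (np.arange(nx) + 0.5) * x_pitch_um
    ys = (np.arange(ny) + 0.5) * y_pitch_um
    r = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
    inner_r = cfg.inner_diameter_um / 2.0
    outer_r = cfg.outer_diameter_um / 2.0

    fov_x = nx * x_pitch_um
    fov_y = ny * y_pitch_um
    if (
        cx - outer_r < 0 or cx + outer_r > fov_x
        or cy - outer_r < 0 or cy + outer_r > fov_y
    ):
        ring_area = math.pi * (outer_r**2 - inner_r**2)
        mask_area = float(((r >= inner_r) & (r < outer_r)).sum()) * x_pitch_um * y_pitch_um
        clipped = max(0.0, 1.0 - mask_area / ring_area)
        raise VolumeValidationError(
            f"annulus exceeds the field of view ({clipped:.1%} clipped)"
        )

    annulus = (r >= inner_r) & (r < outer_r)
    th = math.radians(cfg.orientation_deg)
    side = (xs[None, :] - cx) * math.sin(th) + (cy - ys[:, None]) * math.cos(th)
    superior = annulus & (side > 0)
    inferior = annulus & ~superior
    return AnnulusMask(
        annulus=annulus,
        superior=superior,
        inferior=inferior,
        center_um=(cx, cy),
        inner_diameter_um=cfg.inner_diameter_um,
        outer_diameter_um=cfg.outer_diameter_um,
        orientation_deg=cfg.orientation_deg,
    )


def find_onh_center(volume: OCTVolume, layer_map: LayerMap | None = None) -> tuple[float, float]:
    """Fallback ONH locator: centroid of the darkest en-face disc.

    The ONH is layerless, so the en-face mean intensity has a local minimum
    there.  Intended for data without ground truth; phantom truth or config
    should be preferred when available.
    """
    enface = np.abs(volume.co_channel).mean(axis=(0, 3))
    sm = ndimage.gaussian_filter(enface, sigma=2.0)
    thr = np.percentile(sm, 5)
    mask = sm <= thr
    lab, n = ndimage.label(mask)
    if n == 0:
        iy, ix = np.unravel_index(np.argmin(sm), sm.shape)
    else:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        cy_cx = ndimage.center_of_mass(mask, lab, index=int(np.argmax(sizes)) + 1)
        iy, ix = cy_cx
    md = volume.metadata
    return ((ix + 0.5) * md.x_pitch_um, (iy + 0.5) * md.y_pitch_um)


def compute_thickness(
    layer_map: LayerMap,
    annulus: AnnulusMask,
    eye_id: str = "",
    group: str = "wildtype",
    age_weeks: float = 1.0,
) -> ThicknessRecord:
    """Mean total/inner/outer thickness over the whole/superior/inferior annulus."""
    record = ThicknessRecord(eye_id=eye_id, group=group, age_weeks=age_weeks)
    maps = {
        "total": layer_map.total_um,
        "inner": layer_map.inner_um,
        "outer": layer_map.outer_um,
    }
    for region in ("whole", "superior", "inferior"):
        sel = annulus.region(region) & layer_map.valid
        if not sel.any():
            raise VolumeValidationError(f"no valid pixels in the {region} region")
        for comp, m in maps.items():
            record.metrics[f"{comp}_{region}"] = float(m[sel].mean())
    return record


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def fit_age_pretest(records: pd.DataFrame, metric: str) -> tuple[float, float]:
    """OLS thickness ~ age for one group: (slope um/week, two-sided slope p)."""
    if len(records) < 3:
        raise VolumeValidationError("pretest needs at least 3 records")
    ages = records["age_weeks"].to_numpy(float)
    if np.unique(ages).size < 2:
        raise VolumeValidationError("pretest needs at least 2 distinct ages")
    res = stats.linregress(ages, records[metric].to_numpy(float))
    return float(res.slope), float(res.pvalue)


def compare_groups(
    records: pd.DataFrame, metric: str, config: StatsConfig | None = None
) -> GroupComparison:
    """Pretest each group; ANCOVA on the age x group interaction if both are
    age-dependent, otherwise one-way ANOVA on the group means."""
    cfg = config or StatsConfig()
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise VolumeValidationError(f"expected 2 groups, got {groups}")
    pretest_p: dict[str, float] = {}
    slopes: dict[str, float] = {}
    for g in groups:
        slope, p = fit_age_pretest(records[records["group"] == g], metric)
        pretest_p[g] = p
        slopes[g] = slope

    alpha = cfg.alpha
    df = records[["age_weeks", "group", metric]].rename(columns={metric: "value"})
    if all(p < alpha for p in pretest_p.values()):
        model = smf.ols("value ~ age_weeks * C(group)", data=df).fit()
        table = anova_lm(model, typ=2)
        p_int = float(table.loc["age_weeks:C(group)", "PR(>F)"])
        additive = smf.ols("value ~ age_weeks + C(group)", data=df).fit()
        p_adj = float(anova_lm(additive, typ=2).loc["C(group)", "PR(>F)"])
        return GroupComparison(
            metric=metric,
            pretest_p=pretest_p,
            slopes_um_per_week=slopes,
            chosen_test="ANCOVA",
            p_value=p_int,
            p_adjusted_means=p_adj,
        )
    vals = [df.loc[df["group"] == g, "value"].to_numpy(float) for g in groups]
    p_anova = float(stats.f_oneway(*vals).pvalue)
    return GroupComparison(
        metric=metric,
        pretest_p=pretest_p,
        slopes_um_per_week=slopes,
        chosen_test="ANOVA",
        p_value=p_anova,
    )


def compare_all_metrics(
    records: pd.DataFrame, config: StatsConfig | None = None
) -> pd.DataFrame:
    """Run the comparison for all nine metrics; one row per metric.

    Slopes are reported as positive thinning magnitudes (sign retained in the
    ``slope_signed_*`` columns).  An optional Bonferroni flag multiplies the
    comparison p-values by the number of metrics.
    """
    cfg = config or StatsConfig()
    rows = []
    for metric in THICKNESS_METRICS:
        c = compare_groups(records, metric, cfg)
        groups = sorted(c.pretest_p)
        p = c.p_value
        if cfg.bonferroni:
            p = min(1.0, p * len(THICKNESS_METRICS))
        row = {
            "metric": metric,
            "chosen_test": c.chosen_test,
            "p_comparison": p,
        }
        for g in groups:
            row[f"pretest_p_{g}"] = c.pretest_p[g]
            row[f"slope_signed_{g}"] = c.slopes_um_per_week[g]
            row[f"thinning_um_per_week_{g}"] = -c.slopes_um_per_week[g]
        rows.append(row)
    return pd.DataFrame(rows)
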