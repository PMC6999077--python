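"""Cortical plaque-load morphometry from brightfield immunostain images.

DAB-stained amyloid deposits appear brown on a pink tissue background.  The
segmentation selects brown by an HSV window (hue 10-40 degrees, saturated,
not too bright), counts connected components above a minimum equivalent area
inside a user-supplied cortex mask, and reports the plaque load in plaques
per mm^2.  A linear plaque-load-vs-age regression summarizes a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import color

from .config import HistologyConfig
from .errors import VolumeValidationError

__all__ = [
    "PlaqueQuantification",
    "PlaqueAgeTrend",
    "segment_plaques",
    "fit_plaque_trend",
]


@dataclass
class PlaqueQuantification:
    image_id: str
    age_weeks: float
    plaque_count: int
    region_area_mm2: float
    plaque_load_per_mm2: float
    plaque_mask: np.ndarray


@dataclass
class PlaqueAgeTrend:
    slope_per_mm2_per_week: float
    intercept: float
    r_squared: float
    p_value: float


def segment_plaques(
    rgb: np.ndarray,
    region_mask: np.ndarray,
    pixel_size_um: float,
    image_id: str = "",
    age_weeks: float = 1.0,
    config: HistologyConfig | None = None,
) -> PlaqueQuantification:
    """Segment brown deposits inside the region mask and compute plaque load.

    Touching deposits merge into one connected component and are counted once.
    """
    cfg = config or HistologyConfig()
    if pixel_size_um is None or pixel_size_um <= 0:
        raise VolumeValidationError("pixel size (um) must be known and positive")
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise VolumeValidationError("region mask is empty")
    img = np.asarray(rgb)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    hsv = color.rgb2hsv(img)
    hue_deg = hsv[..., 0] * 360.0
    brown = (
        (hue_deg >= cfg.hue_min_deg)
        & (hue_deg <= cfg.hue_max_deg)
        & (hsv[..., 1] > cfg.saturation_min)
        & (hsv[..., 2] < cfg.value_max)
        & region_mask
    )
    labels, n = ndimage.label(brown, structure=np.ones((3, 3), bool))
    min_px = cfg.min_area_um2 / (pixel_size_um**2)
    count = 0
    keep = np.zeros_like(brown)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        for k, s in enumerate(sizes, start=1):
            if s >= min_px:
                count += 1
                keep |= labels == k
    area_mm2 = float(region_mask.sum()) * (pixel_size_um**2) / 1e6
    return PlaqueQuantification(
        image_id=image_id,
        age_weeks=age_weeks,
        plaque_count=count,
        region_area_mm2=area_mm2,
        plaque_load_per_mm2=count / area_mm2,
        plaque_mask=keep,
    )


def fit_plaque_trend(quantifications: list[PlaqueQuantification] | pd.DataFrame) -> PlaqueAgeTrend:
    """OLS plaque load ~ age: slope, intercept, R^2, two-sided slope p-value."""
    if isinstance(quantifications, pd.DataFrame):
        df = quantifications
    else:
        df = pd.DataFrame(
            {
                "age_weeks": [q.age_weeks for q in quantifications],
                "plaque_load_per_mm2": [q.plaque_load_per_mm2 for q in quantifications],
            }
        )
    if len(df) < 3:
        raise VolumeValidationError("trend fit needs at least 3 images")
    ages = df["age_weeks"].to_numpy(float)
    if np.unique(ages).size < 2:
        raise VolumeValidationError("trend fit needs at least 2 distinct ages")
    loads = df["plaque_load_per_mm2"].to_numpy(float)
    if np.ptp(loads) == 0:  # constant response: no trend, by definition
        return PlaqueAgeTrend(
            slope_per_mm2_per_week=0.0, intercept=float(loads[0]),
            r_squared=0.0, p_value=1.0,
        )
    res = stats.linregress(ages, loads)
    return PlaqueAgeTrend(
        slope_per_mm2_per_week=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )
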