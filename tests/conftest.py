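"""Shared phantom fixtures.

The standard phantom (session-scoped, generated once) carries every tissue
feature the pipeline stages consume: undulating layers, ONH, two vessel
plexuses, three hyper-reflective foci, one ectopic melanin deposit, axial
motion, and per-repeat phase offsets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from retoct.layers import build_annulus, segment_layers
from retoct.phantom import PhantomConfig, generate_phantom
from retoct.preprocess import detect_rpe_crosspol, flatten_volume

warnings.filterwarnings("ignore", category=FutureWarning)

STD_SHAPE = (5, 100, 128, 256)
SMALL_SHAPE = (5, 64, 96, 224)

STD_HRF = [
    {"x_um": 300, "y_um": 300, "depth_frac": 0.5, "radius_um": 20, "amplitude_factor": 4.0},
    {"x_um": 700, "y_um": 650, "depth_frac": 0.75, "radius_um": 25, "amplitude_factor": 4.0},
    {"x_um": 250, "y_um": 700, "depth_frac": 0.3, "radius_um": 18, "amplitude_factor": 4.0},
]
STD_DEPOSITS = [{"x_um": 650, "y_um": 250, "depth_frac": 0.3, "radius_um": 15}]


def make_std_config(seed: int = 11, **overrides) -> PhantomConfig:
    fields = dict(
        motion={"axial_walk_sigma_px": 0.8, "repeat_phase": True},
        hrf=STD_HRF,
        melanin_deposits=STD_DEPOSITS,
        seed=seed,
    )
    fields.update(overrides)
    return PhantomConfig.default(STD_SHAPE, **fields)


@pytest.fixture(scope="session")
def std_phantom():
    """Fully featured phantom: (volume, truth)."""
    return generate_phantom(make_std_config())


@pytest.fixture(scope="session")
def std_pipeline(std_phantom):
    """Flattened volume, layer map, and annulus for the standard phantom."""
    vol, truth = std_phantom
    rpe, _ = detect_rpe_crosspol(vol)
    flat = flatten_volume(vol, rpe)
    layer_map = segment_layers(flat.volume)
    md = vol.metadata
    annulus = build_annulus(
        (md.n_bscan_locations, md.n_ascans_per_bscan),
        truth.onh_center_um,
        md.x_pitch_um,
        md.y_pitch_um,
    )
    return flat, layer_map, annulus


@pytest.fixture(scope="session")
def small_phantom():
    """Small motion-free, feature-free phantom for fast structural tests."""
    cfg = PhantomConfig.default(SMALL_SHAPE, seed=3)
    return generate_phantom(cfg)
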