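#!/usr/bin/env python
"""Simulate the reference PS-OCT phantom and write it as a volume container.

The phantom carries every contrast the downstream stages quantify: layered
retina with speckle and motion, two decorrelating vessel plexuses, melanin
(RPE/choroid, ONH remnant, one ectopic deposit), and three hyper-reflective
foci.  The volume container goes to scratch/ (it is large); the ground truth
summary goes to results/phantom_truth.json.
"""

import json
from pathlib import Path

import numpy as np
import tifffile

from retoct.io import write_volume
from retoct.phantom import PhantomConfig, generate_phantom

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "phantom"
RESULTS = ROOT / "results"

SEED = 11


def standard_config(seed: int = SEED) -> PhantomConfig:
    return PhantomConfig.default(
        (5, 100, 128, 256),
        seed=seed,
        motion={"axial_walk_sigma_px": 0.8, "repeat_phase": True},
        hrf=[
            {"x_um": 300, "y_um": 300, "depth_frac": 0.5, "radius_um": 20, "amplitude_factor": 4.0},
            {"x_um": 700, "y_um": 650, "depth_frac": 0.75, "radius_um": 25, "amplitude_factor": 4.0},
            {"x_um": 250, "y_um": 700, "depth_frac": 0.3, "radius_um": 18, "amplitude_factor": 4.0},
        ],
        melanin_deposits=[{"x_um": 650, "y_um": 250, "depth_frac": 0.3, "radius_um": 15}],
    )


def main() -> None:
    cfg = standard_config()
    vol, truth = generate_phantom(cfg)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    write_volume(vol, SCRATCH)
    tifffile.imwrite(
        SCRATCH / "truth_boundaries.tif",
        np.stack([truth.ilm_px, truth.opl_px, truth.rpe_px]).astype(np.float32),
    )
    tifffile.imwrite(
        SCRATCH / "truth_vessels.tif",
        np.stack(
            [truth.vessel_enface["SVP"], truth.vessel_enface["DCP"]]
        ).astype(np.uint8),
    )
    RESULTS.mkdir(exist_ok=True)
    summary = {
        "seed": cfg.seed,
        "shape": [cfg.n_repeats, cfg.n_y, cfg.n_x, cfg.n_z],
        "applied_motion_px": truth.shifts_px.tolist(),
        "onh_center_um": truth.onh_center_um,
        "hrf": [
            {"center_um": t["center_um"], "volume_um3": t["volume_um3"]}
            for t in truth.hrf_records
        ],
        "n_melanin_voxels": int(truth.melanin_mask.sum()),
    }
    (RESULTS / "phantom_truth.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"phantom written to {SCRATCH} (shape {vol.shape}); truth summary in results/")


if __name__ == "__main__":
    main()
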