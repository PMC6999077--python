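"""Phase retardation mapping and depolarizing-deposit screening."""

import numpy as np
import pytest
from scipy import stats

from retoct.config import PolarizationConfig
from retoct.io import AcquisitionMetadata, OCTVolume
from retoct.layers import LayerMap
from retoct.phantom import PhantomConfig, generate_phantom
from retoct.polarization import (
    build_expected_mask,
    compute_retardation,
    screen_deposits,
)


def _metadata(shape):
    nr, ny, nx, nz = shape
    return AcquisitionMetadata(
        ascan_rate_hz=83_000.0, n_ascans_per_bscan=nx, n_bscan_locations=ny,
        n_repeats=nr, flyback_time_s=1.5e-3, fov_x_mm=1.0, fov_y_mm=1.0,
        axial_pitch_um=2.0, center_wavelength_nm=840.0, beam_power_mw=2.85,
        eye_id="t", group_label="wildtype", age_weeks=60.0,
    )


def _volume(co_amp, cross_amp, shape=(1, 4, 8, 16)):
    co = np.full(shape, co_amp, np.complex64)
    cross = np.full(shape, cross_amp, np.complex64)
    return OCTVolume(co, cross, _metadata(shape))


def _truth_layer_map(truth, cfg):
    return LayerMap(
        ilm_px=truth.ilm_px.astype(float), opl_px=truth.opl_px.astype(float),
        rpe_px=truth.rpe_px.astype(float), valid=np.ones_like(truth.valid),
        axial_pitch_um=cfg.axial_pitch_um,
        x_pitch_um=1e3 * cfg.fov_x_mm / cfg.n_x,
        y_pitch_um=1e3 * cfg.fov_y_mm / cfg.n_y,
    )


class TestRetardation:
    def test_equal_amplitudes_give_45_degrees(self):
        ret = compute_retardation(_volume(1.0, 1.0))
        assert np.allclose(ret.delta_deg, 45.0)

    def test_limits_zero_and_ninety(self):
        assert np.allclose(compute_retardation(_volume(1.0, 0.0)).delta_deg, 0.0)
        assert np.allclose(compute_retardation(_volume(0.0, 1.0)).delta_deg, 90.0)

    def test_invariant_to_common_amplitude_scaling(self):
        a = compute_retardation(_volume(0.7, 0.3))
        b = compute_retardation(_volume(7.0, 3.0))
        np.testing.assert_allclose(a.delta_deg, b.delta_deg, atol=1e-5)

    def test_literal_convention_swaps_channels(self):
        cfg = PolarizationConfig(literal_channel_convention=True)
        ret = compute_retardation(_volume(1.0, 0.0), cfg)
        assert np.allclose(ret.delta_deg, 90.0)

    def test_phantom_preserving_tissue_is_low_melanin_is_uniform(self, std_phantom):
        vol, truth = std_phantom
        ret = compute_retardation(vol)
        amp = vol.amplitude("combined").mean(axis=0)
        preserving = ~truth.melanin_mask & (amp > 0.3) & truth.valid[:, :, None]
        assert np.percentile(ret.delta_deg[preserving], 95) < 10.0
        # high-SNR melanin voxels: at low SNR the additive noise floor biases
        # the measured angle away from the generated one
        melanin = truth.melanin_mask & (amp > 0.5)
        sample = ret.delta_deg[melanin]
        rng = np.random.default_rng(0)
        sub = rng.choice(sample, 3000, replace=False) / 90.0
        assert stats.kstest(sub, "uniform").pvalue > 0.01


class TestExpectedMask:
    def test_flat_rpe_without_onh_is_a_half_space(self):
        shape = (20, 30)
        lm = LayerMap(
            ilm_px=np.full(shape, 40.0), opl_px=np.full(shape, 80.0),
            rpe_px=np.full(shape, 180.0), valid=np.ones(shape, bool),
            axial_pitch_um=2.0, x_pitch_um=7.8, y_pitch_um=10.0,
        )
        mask = build_expected_mask(lm, 256)
        cut = int(round(180.0 - 5.0 / 2.0))
        assert mask[:, :, cut:].all()
        assert not mask[:, :, :cut].any()

    def test_zero_margins_reduce_to_rpe_slab(self):
        shape = (20, 30)
        lm = LayerMap(
            ilm_px=np.full(shape, 40.0), opl_px=np.full(shape, 80.0),
            rpe_px=np.full(shape, 180.0), valid=np.ones(shape, bool),
            axial_pitch_um=2.0, x_pitch_um=7.8, y_pitch_um=10.0,
        )
        cfg = PolarizationConfig(rpe_margin_um=0.0, onh_margin_um=0.0)
        mask = build_expected_mask(lm, 256, (100.0, 100.0), 0.0, cfg)
        assert mask[:, :, 180:].all() and not mask[:, :, :180].any()

    def test_covers_phantom_melanin(self, std_phantom):
        vol, truth = std_phantom
        cfg_ph = truth.config
        lm = _truth_layer_map(truth, cfg_ph)
        mask = build_expected_mask(
            lm, cfg_ph.n_z, truth.onh_center_um, truth.onh_radius_um
        )
        rpe_choroid = truth.melanin_mask.copy()
        for dm in truth.deposit_masks:
            rpe_choroid &= ~dm  # ectopic deposits are *meant* to be outside
        assert mask[rpe_choroid].mean() >= 0.99


class TestScreening:
    def test_phantom_without_ectopic_melanin_yields_empty_list(self):
        cfg = PhantomConfig.default((5, 64, 96, 224), seed=40)
        vol, truth = generate_phantom(cfg)
        lm = _truth_layer_map(truth, cfg)
        ret = compute_retardation(vol)
        mask = build_expected_mask(lm, cfg.n_z, truth.onh_center_um, truth.onh_radius_um)
        assert screen_deposits(ret, mask, lm) == []

    def test_single_inl_deposit_found_and_labeled(self, std_phantom, std_pipeline):
        _, truth = std_phantom
        flat, lm, _ = std_pipeline
        ret = compute_retardation(flat.volume)
        mask = build_expected_mask(
            lm, flat.volume.n_z, truth.onh_center_um, truth.onh_radius_um
        )
        deposits = screen_deposits(ret, mask, lm)
        assert len(deposits) == 1
        d = deposits[0]
        assert d.layer_label == "inner_retina"
        spec = truth.config.melanin_deposits[0]
        assert d.centroid_um[0] == pytest.approx(spec.x_um, abs=5)
        assert d.centroid_um[1] == pytest.approx(spec.y_um, abs=5)

    def test_component_below_minimum_size_dropped(self):
        cfg = PhantomConfig.default(
            (5, 64, 96, 224), seed=41,
            melanin_deposits=[
                {"x_um": 300, "y_um": 300, "depth_frac": 0.3, "radius_um": 18},
                {"x_um": 700, "y_um": 700, "depth_frac": 0.3, "radius_um": 8},
            ],
        )
        vol, truth = generate_phantom(cfg)
        assert truth.deposit_masks[1].sum() < 27 <= truth.deposit_masks[0].sum()
        lm = _truth_layer_map(truth, cfg)
        ret = compute_retardation(vol)
        mask = build_expected_mask(lm, cfg.n_z, truth.onh_center_um, truth.onh_radius_um)
        deposits = screen_deposits(ret, mask, lm)
        assert len(deposits) == 1
        assert deposits[0].centroid_um[0] == pytest.approx(300, abs=10)

    def test_count_monotone_in_threshold_and_size(self, std_phantom, std_pipeline):
        _, truth = std_phantom
        flat, lm, _ = std_pipeline
        ret = compute_retardation(flat.volume)
        mask = build_expected_mask(
            lm, flat.volume.n_z, truth.onh_center_um, truth.onh_radius_um
        )
        counts_thr = [
            len(screen_deposits(ret, mask, lm, PolarizationConfig(delta_threshold_deg=t)))
            for t in (20.0, 30.0, 45.0, 60.0)
        ]
        assert counts_thr == sorted(counts_thr, reverse=True)
        counts_size = [
            len(screen_deposits(ret, mask, lm, PolarizationConfig(min_component_voxels=s)))
            for s in (8, 27, 64)
        ]
        assert counts_size == sorted(counts_size, reverse=True)
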