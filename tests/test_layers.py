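"""Layer segmentation, annulus geometry, thickness metrics, group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retoct.config import AnnulusConfig, SegmentationConfig
from retoct.errors import VolumeValidationError
from retoct.io import AcquisitionMetadata, OCTVolume
from retoct.layers import (
    build_annulus,
    compare_groups,
    compute_thickness,
    fit_age_pretest,
    segment_layers,
)
from retoct.phantom import CohortConfig, GroupCohort, generate_cohort


def _metadata(shape, fov=1.0, pitch=2.0):
    nr, ny, nx, nz = shape
    return AcquisitionMetadata(
        ascan_rate_hz=83_000.0, n_ascans_per_bscan=nx, n_bscan_locations=ny,
        n_repeats=nr, flyback_time_s=1.5e-3, fov_x_mm=fov, fov_y_mm=fov,
        axial_pitch_um=pitch, center_wavelength_nm=840.0, beam_power_mw=2.85,
        eye_id="t", group_label="wildtype", age_weeks=60.0,
    )


def _step_volume(boundaries=(50, 120, 180), shape=(1, 12, 16, 256)):
    """Noise-free piecewise-constant retina-like intensity profile."""
    ilm, opl, rpe = boundaries
    nr, ny, nx, nz = shape
    prof = np.full(nz, 0.05)
    prof[ilm:opl] = 0.9        # inner retina + OPL band (bright)
    prof[opl:rpe] = 0.3        # outer retina
    prof[rpe:] = 0.05          # below the RPE
    co = np.broadcast_to(prof, shape).astype(np.complex64).copy()
    return OCTVolume(co, np.zeros_like(co), _metadata(shape))


class TestSegmentation:
    def test_noise_free_step_boundaries_recovered_exactly(self):
        vol = _step_volume((50, 120, 180))
        cfg = SegmentationConfig(smooth_sigma_y=0, smooth_sigma_x=0, smooth_sigma_z=0)
        peak = np.full((12, 16), 178.0)  # anterior of the posterior step
        lm = segment_layers(vol, cfg, rpe_peak_px=peak)
        assert np.allclose(lm.ilm_px, 50)
        assert np.allclose(lm.opl_px, 120)
        assert np.allclose(lm.rpe_px, 180)

    def test_speckled_phantom_boundaries_within_two_pixels(self, std_phantom, std_pipeline):
        _, truth = std_phantom
        flat, lm, _ = std_pipeline
        sel = truth.valid & lm.valid
        for det, tru in (
            (lm.ilm_px, truth.ilm_px),
            (lm.opl_px, truth.opl_px),
            (lm.rpe_px, truth.rpe_px),
        ):
            err = np.abs(det - (tru + flat.shift_px))[sel]
            assert (err <= 2).mean() >= 0.95

    def test_inner_plus_outer_equals_total(self, std_pipeline):
        _, lm, _ = std_pipeline
        np.testing.assert_allclose(
            lm.inner_um + lm.outer_um, lm.total_um, rtol=0, atol=1e-9
        )


class TestAnnulus:
    def test_mask_equals_brute_force_physical_distance(self):
        xp, yp = 7.8125, 10.0
        ann = build_annulus((100, 128), (500.0, 500.0), xp, yp)
        brute = np.zeros((100, 128), bool)
        for iy in range(100):
            for ix in range(128):
                r = np.hypot((ix + 0.5) * xp - 500.0, (iy + 0.5) * yp - 500.0)
                brute[iy, ix] = 250.0 <= r < 450.0
        np.testing.assert_array_equal(ann.annulus, brute)

    def test_halves_partition_the_annulus(self):
        ann = build_annulus((100, 128), (500.0, 500.0), 7.8125, 10.0)
        assert not (ann.superior & ann.inferior).any()
        np.testing.assert_array_equal(ann.superior | ann.inferior, ann.annulus)

    def test_degenerate_equal_diameters_empty(self):
        cfg = AnnulusConfig(inner_diameter_um=500, outer_diameter_um=500)
        ann = build_annulus((100, 128), (500.0, 500.0), 7.8125, 10.0, cfg)
        assert not ann.annulus.any()

    def test_annulus_outside_fov_rejected(self):
        with pytest.raises(VolumeValidationError, match="clipped"):
            build_annulus((100, 128), (100.0, 100.0), 7.8125, 10.0)

    def test_rotated_split_still_partitions(self):
        cfg = AnnulusConfig(orientation_deg=25.0)
        ann = build_annulus((100, 128), (500.0, 500.0), 7.8125, 10.0, cfg)
        np.testing.assert_array_equal(ann.superior | ann.inferior, ann.annulus)
        assert 0.4 < ann.superior.sum() / ann.annulus.sum() < 0.6


class TestThickness:
    def _constant_layer_map(self, total_um=220.0, inner_um=130.0, shape=(100, 128)):
        from retoct.layers import LayerMap

        pitch = 2.0
        ilm = np.full(shape, 40.0)
        opl = ilm + inner_um / pitch
        rpe = ilm + total_um / pitch
        return LayerMap(
            ilm_px=ilm, opl_px=opl, rpe_px=rpe, valid=np.ones(shape, bool),
            axial_pitch_um=pitch, x_pitch_um=7.8125, y_pitch_um=10.0,
        )

    def test_constant_phantom_exact_metrics(self):
        lm = self._constant_layer_map()
        ann = build_annulus((100, 128), (500.0, 500.0), 7.8125, 10.0)
        rec = compute_thickness(lm, ann)
        for region in ("whole", "superior", "inferior"):
            assert rec.metrics[f"total_{region}"] == pytest.approx(220.0)
            assert rec.metrics[f"inner_{region}"] == pytest.approx(130.0)
            assert rec.metrics[f"outer_{region}"] == pytest.approx(90.0)

    def test_total_is_inner_plus_outer_in_record(self, std_pipeline):
        _, lm, ann = std_pipeline
        rec = compute_thickness(lm, ann)
        for region in ("whole", "superior", "inferior"):
            assert rec.metrics[f"total_{region}"] == pytest.approx(
                rec.metrics[f"inner_{region}"] + rec.metrics[f"outer_{region}"],
                abs=1e-6,
            )

    def test_superior_only_thinning_shows_up_in_superior_mean(self):
        lm = self._constant_layer_map()
        ann = build_annulus((100, 128), (500.0, 500.0), 7.8125, 10.0)
        lm.rpe_px[ann.superior] -= 10.0 / lm.axial_pitch_um  # thin superior by 10 um
        rec = compute_thickness(lm, ann)
        assert rec.metrics["total_inferior"] - rec.metrics["total_superior"] == pytest.approx(
            10.0, abs=0.5
        )


class TestStatistics:
    def test_noiseless_line_recovers_slope_with_zero_p(self):
        ages = np.linspace(45, 104, 30)
        df = pd.DataFrame({"age_weeks": ages, "m": 250 - 0.37 * ages})
        slope, p = fit_age_pretest(df, "m")
        assert slope == pytest.approx(-0.37, abs=1e-9)
        assert p < 1e-12

    def test_pretest_null_p_is_uniform(self):
        # no age dependence: the slope p-value must be U(0,1)
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(2000):
            ages = rng.uniform(45, 104, 44)
            df = pd.DataFrame({"age_weeks": ages, "m": rng.normal(220, 5, 44)})
            ps.append(fit_age_pretest(df, "m")[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_flat_groups_take_the_anova_branch(self):
        rng = np.random.default_rng(1)
        rows = []
        for g in ("transgenic", "wildtype"):
            ages = rng.uniform(45, 104, 30)
            rows.append(pd.DataFrame({
                "group": g, "age_weeks": ages, "m": rng.normal(220, 5, 30),
            }))
        comp = compare_groups(pd.concat(rows), "m")
        assert comp.chosen_test == "ANOVA"
        assert all(p >= 0.05 for p in comp.pretest_p.values())

    def test_age_dependent_groups_take_the_ancova_branch(self):
        cfg = CohortConfig(seed=5)
        df = generate_cohort(cfg)
        comp = compare_groups(df, "total_whole")
        assert comp.chosen_test == "ANCOVA"
        assert comp.p_adjusted_means is not None

    def test_distinct_slopes_detected_by_ancova(self):
        # slopes -0.37 vs -0.26 with tiny residual noise: the age x group
        # interaction must be significant in >= 95% of replicates
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = CohortConfig(
                transgenic=GroupCohort(n_eyes=40, age_min_weeks=45, age_max_weeks=104,
                                       baseline_um=250, slope_um_per_week=0.37, sigma_um=0.5),
                wildtype=GroupCohort(n_eyes=40, age_min_weeks=45, age_max_weeks=104,
                                     baseline_um=250, slope_um_per_week=0.26, sigma_um=0.5),
                seed=seed,
            )
            comp = compare_groups(generate_cohort(cfg), "total_whole")
            if comp.chosen_test == "ANCOVA" and comp.p_value < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"age_weeks": [60, 60, 60], "m": [1, 2, 3]})
        with pytest.raises(VolumeValidationError):
            fit_age_pretest(df, "m")
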