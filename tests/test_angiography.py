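"""Complex-difference angiography, binarization pipeline, vessel metrics."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

from retoct.angiography import (
    binarize_vessels,
    bulk_phase_correct,
    compute_octa,
    enface_projection,
    octa_volume,
    vessel_density,
    weber_contrast,
)
from retoct.config import AnnulusConfig
from retoct.errors import ExclusionError, NoContrastError, VolumeValidationError
from retoct.layers import build_annulus
from retoct.phantom import PhantomConfig, generate_phantom


def _speckle(shape, seed):
    rng = np.random.default_rng(seed)
    return (
        (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
    ).astype(np.complex64)


class TestBulkPhase:
    def test_global_phase_is_removed(self):
        base = _speckle((16, 32), 0)
        reps = np.stack([base, base * np.exp(1j * 1.3), base * np.exp(1j * 2.9)])
        corrected, excluded = bulk_phase_correct(reps)
        assert excluded == []
        octa = compute_octa(corrected)
        assert octa.decorrelation.max() < 1e-5

    def test_corrupted_repeat_is_excluded(self):
        base = _speckle((16, 32), 1)
        reps = np.stack([base] * 4 + [_speckle((16, 32), 2)])
        corrected, excluded = bulk_phase_correct(reps)
        assert excluded == [4]
        assert corrected.shape[0] == 4

    def test_static_phantom_keeps_all_repeats(self, small_phantom):
        vol, _ = small_phantom
        _, excluded = bulk_phase_correct(vol.co_channel[:, 10])
        assert excluded == []

    def test_all_repeats_corrupt_raises(self):
        reps = np.stack([_speckle((16, 32), s) for s in range(4)])
        with pytest.raises(ExclusionError):
            bulk_phase_correct(reps)


class TestOCTA:
    def test_identical_repeats_give_zero(self):
        base = _speckle((8, 8), 3)
        octa = compute_octa(np.stack([base, base, base]))
        assert octa.decorrelation.max() == 0
        assert octa.n_pairs == 2

    def test_pixel_arithmetic(self):
        a = np.full((1, 1), 3 + 4j, np.complex64)
        b = np.zeros((1, 1), np.complex64)
        octa = compute_octa(np.stack([a, b]))
        assert octa.decorrelation[0, 0] == pytest.approx(5.0)

    def test_flow_voxels_far_exceed_static(self, std_phantom, std_pipeline):
        _, truth = std_phantom
        flat, lm, _ = std_pipeline
        octa, _ = octa_volume(flat.volume)
        # vessel truth in flattened coordinates
        shift = flat.shift_px
        inside = np.zeros(octa.shape, bool)
        for plexus in ("SVP", "DCP"):
            m = truth.vessel_volume[plexus]
            for y in range(m.shape[0]):
                for x in range(m.shape[1]):
                    s = shift[y, x]
                    inside[y, x] = np.roll(m[y, x], s)
        assert octa[inside].mean() > 5 * octa[~inside].mean()

    def test_invariant_to_global_phase(self):
        # repeats share speckle (static tissue) with a little independent noise
        core = _speckle((16, 32), 5)
        base = np.stack([core + 0.05 * _speckle((16, 32), s) for s in (6, 7, 8)])
        rotated = base * np.exp(1j * 0.7)
        a, _ = bulk_phase_correct(base)
        b, _ = bulk_phase_correct(rotated)
        np.testing.assert_allclose(
            compute_octa(a).decorrelation, compute_octa(b).decorrelation, atol=1e-5
        )


class TestEnface:
    def test_zero_slab_gives_zero_image(self, std_pipeline):
        _, lm, _ = std_pipeline
        octa = np.zeros((100, 128, 256), np.float32)
        assert enface_projection(octa, lm, "SVP").max() == 0

    def test_single_bright_voxel_is_the_max(self, std_pipeline):
        _, lm, _ = std_pipeline
        octa = np.zeros((100, 128, 256), np.float32)
        z = int(lm.ilm_px[50, 60]) + 3
        octa[50, 60, z] = 7.5
        assert enface_projection(octa, lm, "SVP")[50, 60] == pytest.approx(7.5)

    def test_phantom_vessels_separate_from_background(self, std_phantom, std_pipeline):
        from sklearn.metrics import roc_auc_score

        _, truth = std_phantom
        flat, lm, _ = std_pipeline
        octa, _ = octa_volume(flat.volume)
        raw = enface_projection(octa, lm, "SVP")
        # the ONH disc is layerless (no signal), so separation is only
        # defined outside it
        sel = truth.valid.ravel()
        auc = roc_auc_score(
            truth.vessel_enface["SVP"].ravel()[sel], raw.ravel()[sel]
        )
        assert auc > 0.95


class TestBinarization:
    def test_bright_bar_final_map_is_five_pixel_bar(self):
        # brute-force oracle: skeleton of the bar dilated by a 5x5 square
        img = np.zeros((64, 64))
        img[30:33, 8:56] = 1.0
        rng = np.random.default_rng(0)
        img += 0.02 * rng.random((64, 64))
        ef = binarize_vessels(img)
        skel_truth = morphology.skeletonize(img > 0.5)
        brute = ndimage.binary_dilation(
            skel_truth, structure=np.ones((5, 5), bool)
        )
        agreement = (ef.final == brute).mean()
        assert agreement > 0.97
        assert (ef.final & ~brute).sum() <= 0.1 * brute.sum()

    def test_constant_image_raises_no_contrast(self):
        with pytest.raises(NoContrastError, match="contrast"):
            binarize_vessels(np.zeros((32, 32)))

    def test_final_map_contains_skeleton(self, std_phantom, std_pipeline):
        flat, lm, _ = std_pipeline
        octa, _ = octa_volume(flat.volume)
        ef = binarize_vessels(enface_projection(octa, lm, "SVP"))
        assert (ef.final | ~ef.skeleton).all()  # final is a superset

    def test_phantom_dice_against_truth(self, std_phantom, std_pipeline):
        _, truth = std_phantom
        flat, lm, _ = std_pipeline
        octa, _ = octa_volume(flat.volume)
        for plexus in ("SVP", "DCP"):
            raw = enface_projection(octa, lm, plexus)
            ef = binarize_vessels(raw, plexus)
            truth_final = ndimage.binary_dilation(
                morphology.skeletonize(truth.vessel_enface[plexus]),
                structure=np.ones((5, 5), bool),
            )
            dice = 2 * (ef.final & truth_final).sum() / (
                ef.final.sum() + truth_final.sum()
            )
            assert dice >= 0.7


class TestVesselMetrics:
    def _annulus(self):
        return build_annulus((100, 128), (500.0, 500.0), 7.8125, 10.0)

    def test_full_map_gives_hundred_percent(self):
        ann = self._annulus()
        assert vessel_density(np.ones((100, 128), bool), ann) == (100.0, 100.0, 100.0)

    def test_empty_map_gives_zero(self):
        ann = self._annulus()
        assert vessel_density(np.zeros((100, 128), bool), ann) == (0.0, 0.0, 0.0)

    def test_superior_half_fill_matches_brute_force(self):
        ann = self._annulus()
        vd = vessel_density(ann.superior, ann)
        assert vd[1] == pytest.approx(100.0)
        assert vd[2] == pytest.approx(0.0)
        brute = 100.0 * ann.superior.sum() / ann.annulus.sum()
        assert vd[0] == pytest.approx(brute)

    def test_whole_is_count_weighted_mean_of_halves(self):
        ann = self._annulus()
        rng = np.random.default_rng(4)
        vmap = rng.random((100, 128)) < 0.3
        dw, ds, di = vessel_density(vmap, ann)
        ns, ni = ann.superior.sum(), ann.inferior.sum()
        assert dw == pytest.approx((ds * ns + di * ni) / (ns + ni))

    def test_weber_contrast_arithmetic(self):
        ann = self._annulus()
        vmap = ann.superior.copy()
        raw = np.where(vmap, 2.0, 1.0)
        cw, iv, ib = weber_contrast(raw, vmap, ann)
        assert (cw, iv, ib) == (pytest.approx(1.0), pytest.approx(2.0), pytest.approx(1.0))
        cw0, _, _ = weber_contrast(np.ones((100, 128)), vmap, ann)
        assert cw0 == pytest.approx(0.0)

    def test_weber_contrast_orders_plexuses_by_decorrelation(self):
        # SVP fully decorrelated, DCP only partially: the DCP angiogram signal
        # is weaker, so its vessel-background contrast must be lower
        cfg = PhantomConfig.default((5, 64, 96, 224), seed=21)
        raw_cfg = cfg.model_dump()
        for v in raw_cfg["vessels"]:
            v["decorrelation"] = 1.0 if v["plexus"] == "SVP" else 0.5
        cfg = PhantomConfig(**raw_cfg)
        vol, truth = generate_phantom(cfg)
        from retoct.preprocess import detect_rpe_crosspol, flatten_volume
        from retoct.layers import segment_layers

        rpe, _ = detect_rpe_crosspol(vol)
        flat = flatten_volume(vol, rpe)
        lm = segment_layers(flat.volume)
        md = vol.metadata
        ann = build_annulus((64, 96), truth.onh_center_um, md.x_pitch_um, md.y_pitch_um)
        octa, _ = octa_volume(flat.volume)
        cws = {}
        for plexus in ("SVP", "DCP"):
            raw = enface_projection(octa, lm, plexus)
            ef = binarize_vessels(raw, plexus)
            cws[plexus], _, _ = weber_contrast(raw, ef.final, ann)
        assert cws["SVP"] > cws["DCP"]

    def test_monotone_in_decorrelation_fraction(self):
        means = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = PhantomConfig.default(
                (3, 24, 48, 160), with_onh=False, seed=30,
                vessels=[{"plexus": "SVP", "x0_um": 0, "y0_um": 250, "x1_um": 1000,
                          "y1_um": 250, "radius_um": 40, "decorrelation": frac}],
            )
            vol, truth = generate_phantom(cfg)
            octa, _ = octa_volume(vol)
            means.append(octa[truth.vessel_volume["SVP"]].mean())
        assert all(b >= a - 1e-6 for a, b in zip(means, means[1:]))
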