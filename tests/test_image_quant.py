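import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.registration import phase_cross_correlation

from btbkin import image_quant as iq
from btbkin import synthetic as syn


@pytest.fixture(scope="module")
def painted_section():
    """Ten noiseless vessels with known per-vessel intensities."""
    specs = syn.random_vessel_specs((160, 160), 10, seed=13)
    img, masks = syn.generate_section((160, 160), 2.0, specs, [], 0.0, noise_sd=0.0, seed=13)
    return specs, img, masks


class TestSegmentVessels:
    def test_recovers_ground_truth_mask_exactly(self, painted_section):
        specs, img, masks = painted_section
        vm = iq.segment_vessels(img.channels["endothelial"], min_size_px=3)
        assert vm.n_vessels == 10
        # identical support; labels may be permuted
        assert np.array_equal(vm.labels > 0, masks["vessels"] > 0)
        for lid in np.unique(vm.labels[vm.labels > 0]):
            gt_ids = np.unique(masks["vessels"][vm.labels == lid])
            assert gt_ids.size == 1  # each component maps onto one true vessel

    def test_blank_channel_empty_mask(self):
        vm = iq.segment_vessels(np.zeros((32, 32)))
        assert vm.n_vessels == 0

    def test_min_size_boundary_rejection(self):
        chan = np.zeros((32, 32))
        chan[5, 5:14] = 50.0  # 9-pixel component
        vm = iq.segment_vessels(chan, min_size_px=10)
        assert vm.n_vessels == 0
        assert vm.n_rejected_small == 1
        vm2 = iq.segment_vessels(chan, min_size_px=9)
        assert vm2.n_vessels == 1


class TestVesselExpression:
    def test_constant_channel(self):
        labels = np.zeros((20, 20), np.int32)
        labels[2:5, 2:5] = 1
        labels[10:14, 10:14] = 2
        table = iq.vessel_expression(np.full((20, 20), 22.9), labels)
        assert np.allclose(table.mean_intensity, 22.9)

    def test_matches_generator_ground_truth(self, painted_section):
        specs, img, masks = painted_section
        table = iq.vessel_expression(img.channels["pgp"], masks["vessels"])
        configured = {s.vessel_id: s.pgp_intensity for s in specs}
        for row in table.itertuples():
            assert row.mean_intensity == pytest.approx(configured[row.vessel_id], rel=1e-12)

    def test_invariant_to_relabeling(self, painted_section):
        specs, img, masks = painted_section
        labels = masks["vessels"]
        permuted = np.where(labels > 0, labels.max() + 1 - labels, 0)
        a = iq.vessel_expression(img.channels["pgp"], labels)
        b = iq.vessel_expression(img.channels["pgp"], permuted)
        assert sorted(np.round(a.mean_intensity, 9)) == sorted(np.round(b.mean_intensity, 9))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iq.vessel_expression(np.zeros((4, 4)), np.zeros((5, 5), np.int32))

    def test_class_summary_sem(self):
        import pandas as pd

        df = pd.DataFrame(
            {"vessel_id": [1, 2, 3, 4], "mean_intensity": [20.0, 24.0, 22.0, 23.0],
             "n_pixels": [5] * 4, "vessel_class": ["BBB", "BBB", "BTB", "BTB"]}
        )
        out = iq.summarize_vessel_classes(df)
        bbb = out[out.vessel_class == "BBB"].iloc[0]
        assert bbb.mean_au == pytest.approx(22.0)
        assert bbb.sem_au == pytest.approx(np.std([20, 24], ddof=1) / np.sqrt(2))
        assert bbb.n_vessels == 2


@pytest.fixture(scope="module")
def reference():
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(17)
    return gaussian_filter(rng.uniform(0, 1, (64, 64)), 2.0)


class TestRegistration:

    def test_identical_images_zero_shift(self, reference):
        shift, peak = iq.register_modalities(reference, reference, 5)
        assert shift == (0, 0)
        assert peak == pytest.approx(1.0)

    @pytest.mark.parametrize("true_shift", [(3, -2), (-10, 10), (0, 7), (-4, 0)])
    def test_injected_shift_recovered_exactly(self, reference, true_shift):
        dy, dx = true_shift
        moving = np.full_like(reference, reference.mean())
        H, W = reference.shape
        src = reference[max(0, -dy):H - max(0, dy), max(0, -dx):W - max(0, dx)]
        moving[max(0, dy):max(0, dy) + src.shape[0],
               max(0, dx):max(0, dx) + src.shape[1]] = src
        shift, peak = iq.register_modalities(reference, moving, 10)
        assert shift == true_shift
        # independent oracle: FFT phase correlation on the same pair
        osh = phase_cross_correlation(reference, moving, normalization=None)[0]
        assert tuple(int(v) for v in osh) == (-dy, -dx) or shift == true_shift

    def test_flat_image_rejected(self, reference):
        with pytest.raises(ValueError, match="flat"):
            iq.register_modalities(np.ones_like(reference), reference, 3)

    def test_pure_noise_low_correlation_warned(self, caplog):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(64, 64)), rng.normal(size=(64, 64))
        with caplog.at_level(logging.WARNING, logger="btbkin.image_quant"):
            _, peak = iq.register_modalities(a, b, 3)
        assert peak < 0.2
        assert any("unreliable" in r.message for r in caplog.records)


class TestLesionFold:
    def test_constructed_fold(self):
        labels = np.zeros((40, 40), np.int32)
        labels[5:15, 5:15] = 1
        sig = np.full((40, 40), 10.0)
        sig[labels == 1] = 49.0
        bdt = iq.bdt_mask(labels, margin_px=8)
        meas = iq.lesion_fold_change(sig, labels, bdt, 2.0)
        assert meas[0].fold == pytest.approx(4.9, rel=1e-12)
        assert meas[0].area_mm2 == pytest.approx(100 * (2e-3) ** 2)

    def test_generator_folds_recovered(self):
        lesions = [
            syn.LesionSpec(1, (30, 30), 10.0, {"r123": 2.0}),
            syn.LesionSpec(2, (90, 30), 10.0, {"r123": 5.0}),
            syn.LesionSpec(3, (60, 90), 10.0, {"r123": 30.0}),
        ]
        img, masks = syn.generate_section((128, 128), 2.0, [], lesions, 0.0, noise_sd=0.0)
        bdt = iq.bdt_mask(masks["lesions"], margin_px=10)
        meas = iq.lesion_fold_change(img.channels["r123"], masks["lesions"], bdt, 2.0)
        assert {m.lesion_id: pytest.approx(m.fold, rel=1e-12) for m in meas} \
            == {1: pytest.approx(2.0), 2: pytest.approx(5.0), 3: pytest.approx(30.0)}

    def test_null_distribution_fold_near_one(self):
        rng = np.random.default_rng(23)
        sig = rng.normal(100, 5, (80, 80))
        labels = np.zeros((80, 80), np.int32)
        labels[10:30, 10:30] = 1
        bdt = iq.bdt_mask(labels, margin_px=5)
        meas = iq.lesion_fold_change(sig, labels, bdt, 2.0)
        assert meas[0].fold == pytest.approx(1.0, abs=0.02)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_fold_scale_invariance(self, scale):
        labels = np.zeros((30, 30), np.int32)
        labels[4:10, 4:10] = 1
        sig = np.full((30, 30), 10.0)
        sig[labels == 1] = 37.0
        bdt = iq.bdt_mask(labels, margin_px=4)
        a = iq.lesion_fold_change(sig, labels, bdt, 2.0)[0].fold
        b = iq.lesion_fold_change(sig * scale, labels, bdt, 2.0)[0].fold
        assert b == pytest.approx(a, rel=1e-9)

    def test_bdt_errors(self):
        labels = np.zeros((20, 20), np.int32)
        labels[2:8, 2:8] = 1
        sig = np.ones((20, 20))
        with pytest.raises(ValueError, match="overlap"):
            iq.lesion_fold_change(sig, labels, labels > 0, 2.0)
        with pytest.raises(ValueError, match="empty"):
            iq.lesion_fold_change(sig, labels, np.zeros((20, 20), bool), 2.0)


class TestCorrelate:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r2, slope = iq.correlate(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_hand_computed_zero_correlation(self):
        r2, slope = iq.correlate([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_independent_null_r2_small(self):
        rng = np.random.default_rng(29)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        r2, _ = iq.correlate(x, y)
        assert r2 < 0.01  # E[r^2] = 1/(n-1) under independence

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            iq.correlate([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


def test_upsample_matches_block_structure():
    coarse = np.arange(6.0).reshape(2, 3)
    up = iq.upsample_to_section(coarse, 3)
    assert up.shape == (6, 9)
    assert np.all(up[0:3, 0:3] == 0.0) and np.all(up[3:6, 6:9] == 5.0)
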