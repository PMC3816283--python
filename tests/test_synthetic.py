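import numpy as np
import pytest

from btbkin import synthetic as syn


class TestStandards:
    def test_noiseless_line(self):
        df = syn.generate_standards([0.0, 1.0, 2.0], 100.0, 0.0, 0.0, 1, seed=0)
        ipg = df.sum_intensity / df.mass_g
        assert np.allclose(ipg, [0.0, 100.0, 200.0])

    def test_pure_background(self):
        df = syn.generate_standards([0.0], 100.0, 50.0, 0.0, 1, seed=0)
        assert (df.sum_intensity / df.mass_g).iloc[0] == pytest.approx(50.0)

    def test_seed_determinism(self):
        a = syn.generate_standards([0, 1, 2], 100.0, 50.0, 5.0, 10, seed=4)
        b = syn.generate_standards([0, 1, 2], 100.0, 50.0, 5.0, 10, seed=4)
        assert a.equals(b)
        c = syn.generate_standards([0, 1, 2], 100.0, 50.0, 5.0, 10, seed=5)
        assert not a.equals(c)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_standards([0, 1, 2], 100.0, 0.0, -1.0, 1, seed=0)


class TestPerfusionSeries:
    def test_worked_example_qstar(self):
        recs = syn.generate_perfusion_series(0.12, 0.015, 50.0, [120.0], 0.0, 1, seed=0)
        assert recs[0].qstar_ug_per_g == pytest.approx(1.47, abs=1e-12)

    def test_impermeant_constant_ratio(self):
        recs = syn.generate_perfusion_series(0.0, 0.015, 50.0, [30, 60, 120], 0.0, 2, seed=0)
        assert all(r.uptake_ml_per_g == pytest.approx(0.015) for r in recs)

    def test_seed_determinism(self):
        kw = dict(noise_cv=0.1, n_per_time=5, seed=9)
        a = syn.generate_perfusion_series(0.12, 0.015, 50.0, [30, 60, 90, 120], **kw)
        b = syn.generate_perfusion_series(0.12, 0.015, 50.0, [30, 60, 90, 120], **kw)
        assert a == b

    def test_substreams_independent_of_other_artifacts(self):
        """Generating extra artifacts does not perturb an existing stream."""
        a = syn.generate_perfusion_series(0.12, 0.015, 50.0, [60.0], 0.1, 3, seed=2)
        syn.generate_standards([0, 1], 10.0, 0.0, 1.0, 5, seed=2)
        b = syn.generate_perfusion_series(0.12, 0.015, 50.0, [60.0], 0.1, 3, seed=2)
        assert a == b

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_perfusion_series(0.12, 0.015, 0.0, [60.0])
        with pytest.raises(ValueError, match="window"):
            syn.generate_perfusion_series(0.12, 0.015, 50.0, [10.0])


class TestSection:
    def test_single_vessel_exact_mean(self):
        v = syn.VesselSpec(1, (20, 20), (70, 70), 3.0, 22.9)
        img, masks = syn.generate_section((96, 96), 2.0, [v], [], 0.0, noise_sd=0.0, seed=0)
        m = masks["vessels"] == 1
        assert m.sum() > 0
        assert img.channels["pgp"][m].mean() == pytest.approx(22.9, rel=1e-12)
        assert np.all(img.channels["endothelial"][~m] == 0)

    def test_null_lesion_identical_inside_and_outside(self):
        les = syn.LesionSpec(1, (40, 40), 15.0, {"r123": 1.0})
        img, masks = syn.generate_section((96, 96), 2.0, [], [les], 0.0, noise_sd=0.0, seed=0)
        r = img.channels["r123"]
        inside = r[masks["lesions"] == 1]
        outside = r[masks["lesions"] == 0]
        assert inside.mean() == pytest.approx(outside.mean(), rel=1e-12)

    def test_amplification_exact_ratio(self):
        les = syn.LesionSpec(1, (40, 40), 15.0, {"r123": 4.9})
        img, masks = syn.generate_section((96, 96), 2.0, [], [les], 0.0, noise_sd=0.0, seed=0)
        r = img.channels["r123"]
        ratio = r[masks["lesions"] == 1].mean() / r[masks["lesions"] == 0].mean()
        assert ratio == pytest.approx(4.9, rel=1e-12)

    def test_overlapping_lesions_rejected(self):
        lesions = [
            syn.LesionSpec(1, (40, 40), 15.0, {"r123": 1.0}),
            syn.LesionSpec(2, (45, 45), 15.0, {"r123": 2.0}),
        ]
        with pytest.raises(ValueError, match="overlap"):
            syn.generate_section((96, 96), 2.0, [], lesions)

    def test_subpixel_vessel_skipped_with_warning(self):
        v = syn.VesselSpec(1, (20, 20), (70, 70), 0.5, 22.9)
        with pytest.warns(UserWarning, match="skipped"):
            img, masks = syn.generate_section((96, 96), 2.0, [v], [])
        assert masks["vessels"].max() == 0

    def test_channel_shapes_and_names(self):
        img, _ = syn.generate_section((64, 48), 2.0, [], [])
        assert set(img.channels) == {"nuclei", "endothelial", "pgp", "r123"}
        assert img.shape == (64, 48)

    def test_seed_determinism_with_noise(self):
        kw = dict(blur_sigma=1.0, noise_sd=2.0, seed=3)
        a, _ = syn.generate_section((64, 64), 2.0, [], [], **kw)
        b, _ = syn.generate_section((64, 64), 2.0, [], [], **kw)
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])


@pytest.fixture()
def lesion_section():
    lesions = [
        syn.LesionSpec(1, (30, 30), 12.0, {"aib": 4.9}),
        syn.LesionSpec(2, (90, 90), 14.0, {"aib": 30.0}),
    ]
    _, masks = syn.generate_section((128, 128), 2.0, [], lesions, 0.0, noise_sd=0.0, seed=0)
    return masks["lesions"]


class TestAutoradiograph:
    def test_fold_exact_before_noise(self, lesion_section):
        ar = syn.generate_autoradiograph(lesion_section, {1: 4.9, 2: 30.0}, 4, 50.0)
        bg = ar.image[ar.background_mask].mean()
        assert bg == pytest.approx(50.0, rel=1e-12)
        assert ar.image[ar.lesion_labels == 1].mean() / bg == pytest.approx(4.9, rel=1e-12)
        assert ar.image[ar.lesion_labels == 2].mean() / bg == pytest.approx(30.0, rel=1e-12)

    def test_downsample_dimensions(self, lesion_section):
        ar = syn.generate_autoradiograph(lesion_section, {1: 2.0, 2: 2.0}, 4, 50.0)
        assert ar.image.shape == (32, 32)

    def test_known_shift_moves_content(self, lesion_section):
        a0 = syn.generate_autoradiograph(lesion_section, {1: 4.9, 2: 30.0}, 1, 50.0, (0, 0))
        a1 = syn.generate_autoradiograph(lesion_section, {1: 4.9, 2: 30.0}, 1, 50.0, (3, -2))
        assert np.array_equal(a1.image[3:, :-2], a0.image[:-3, 2:])

    def test_invalid_parameters(self, lesion_section):
        with pytest.raises(ValueError):
            syn.generate_autoradiograph(lesion_section, {1: 0.0}, 4)
        with pytest.raises(ValueError):
            syn.generate_autoradiograph(lesion_section, {1: 2.0}, 0)


class TestRandomSpecs:
    def test_vessels_disjoint_and_in_bounds(self):
        specs = syn.random_vessel_specs((192, 192), 12, seed=1)
        assert len(specs) == 12
        img, masks = syn.generate_section((192, 192), 2.0, specs, [])
        labels = masks["vessels"]
        ids = set(np.unique(labels)) - {0}
        assert ids == {s.vessel_id for s in specs}
        assert all(s.pgp_intensity >= 0.5 for s in specs)

    def test_lesions_disjoint_positive_folds(self):
        specs = syn.random_lesion_specs((256, 256), 4, seed=2)
        assert len(specs) == 4
        for s in specs:
            assert s.folds["aib"] > 0 and s.folds["r123"] > 0
        # disjointness enforced by generate_section not raising
        syn.generate_section((256, 256), 2.0, [], specs)

    def test_ground_truth_json_round_trip(self, tmp_path):
        gt = syn.GroundTruth(0.12, 0.015, 1000.0, 50.0,
                             {1: {"aib": 4.9, "r123": 0.98}}, {1: 22.9, 2: 22.6}, seed=3)
        gt.to_json(tmp_path / "gt.json")
        assert syn.GroundTruth.from_json(tmp_path / "gt.json") == gt
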