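"""Synthetic scene construction, label encoding and dataset generation."""

import numpy as np
import pytest

from sfdibruise import forward, invert, synth


class TestMakeFruitMap:
    def test_zero_severity_is_uniform(self):
        spec = synth.FruitSceneSpec(fruit_kind="apple", severity=0.0, size=64)
        opmap, bruise, _ = synth.make_fruit_map(spec)
        assert np.all(opmap.mu_s_prime == 1.726)
        assert not bruise.any()

    def test_full_severity_apple_reaches_bruised_value(self):
        spec = synth.FruitSceneSpec(fruit_kind="apple", severity=1.0, size=64)
        opmap, bruise, sound = synth.make_fruit_map(spec)
        assert np.allclose(opmap.mu_s_prime[bruise], 1.215)
        assert np.allclose(opmap.mu_s_prime[sound], 1.726)

    def test_half_severity_interpolates(self):
        spec = synth.FruitSceneSpec(fruit_kind="apple", severity=0.5, size=64)
        opmap, bruise, _ = synth.make_fruit_map(spec)
        assert np.allclose(opmap.mu_s_prime[bruise], (1.726 + 1.215) / 2)

    def test_deterministic_under_seed(self):
        spec = synth.FruitSceneSpec(fruit_kind="pear", size=64, seed=11)
        m1, _, _ = synth.make_fruit_map(spec)
        m2, _, _ = synth.make_fruit_map(spec)
        np.testing.assert_array_equal(m1.mu_s_prime, m2.mu_s_prime)

    def test_pear_scatters_more_than_apple(self):
        a, _, _ = synth.make_fruit_map(synth.FruitSceneSpec("apple", size=32))
        p, _, _ = synth.make_fruit_map(synth.FruitSceneSpec("pear", size=32))
        assert a.mu_s_prime.mean() < p.mu_s_prime.mean()

    def test_pear_speckle_is_multiplicative_noise(self):
        spec = synth.FruitSceneSpec("pear", severity=0.0, size=64, seed=5)
        opmap, _, _ = synth.make_fruit_map(spec)
        rel = opmap.mu_s_prime / 2.102
        assert 0.01 < rel.std() < 0.1  # near the configured 3% sd

    def test_bruise_and_sound_masks_equal_area(self):
        spec = synth.FruitSceneSpec("apple", size=128, bruise_radius=15.0)
        _, bruise, sound = synth.make_fruit_map(spec)
        assert abs(bruise.sum() - sound.sum()) / bruise.sum() < 0.05
        assert not (bruise & sound).any()

    def test_oversized_bruise_rejected(self):
        with pytest.raises(ValueError):
            synth.make_fruit_map(
                synth.FruitSceneSpec("apple", size=32, bruise_radius=60.0)
            )


class TestRGBLabel:
    def test_endpoints(self):
        opmap = synth.OpticalPropertyMap(
            np.full((2, 2), 0.5), np.full((2, 2), 4.0), pixel_size=1.0
        )
        label = synth.encode_rgb_label(opmap)
        assert np.all(label[..., 0] == 255)
        assert np.all(label[..., 1] == 255)
        assert np.all(label[..., 2] == 0)

    def test_round_trip_within_quantization(self):
        rng = np.random.default_rng(8)
        opmap = synth.OpticalPropertyMap(
            rng.uniform(0.0, 0.5, (16, 16)),
            rng.uniform(0.05, 4.0, (16, 16)),
            pixel_size=1.0,
        )
        decoded = synth.decode_rgb_label(synth.encode_rgb_label(opmap), 1.0)
        assert np.abs(decoded.mu_a - opmap.mu_a).max() <= 0.5 / 510 + 1e-12
        assert np.abs(decoded.mu_s_prime - opmap.mu_s_prime).max() <= 4 / 510 + 1e-12

    def test_out_of_range_rejected(self):
        opmap = synth.OpticalPropertyMap(
            np.full((2, 2), 0.6), np.full((2, 2), 1.0), pixel_size=1.0
        )
        with pytest.raises(ValueError):
            synth.encode_rgb_label(opmap)


class TestRenderStack:
    def test_zero_modulation_collapses_to_dc(self, apple_map_64):
        opmap, _, _ = apple_map_64
        stack = synth.render_stack(opmap, a1=0.0)
        np.testing.assert_array_equal(stack.I1, stack.I_dc)
        np.testing.assert_array_equal(stack.I2, stack.I3)

    def test_noise_reproducible_under_seed(self, apple_map_64):
        opmap, _, _ = apple_map_64
        s1 = synth.render_stack(opmap, noise_sd=0.01, seed=4)
        s2 = synth.render_stack(opmap, noise_sd=0.01, seed=4)
        np.testing.assert_array_equal(s1.I1, s2.I1)

    def test_reference_self_calibration(self, reference_64):
        rd_dc, rd_ac = synth.demodulate_scene(reference_64, reference_64)
        np.testing.assert_allclose(rd_dc.Rd, 0.99, rtol=1e-12)
        np.testing.assert_allclose(rd_ac.Rd, 0.99, rtol=1e-9)

    def test_negative_frequency_rejected(self, apple_map_64):
        with pytest.raises(ValueError):
            synth.render_stack(apple_map_64[0], fx_ac=-0.1)


class TestFullRoundTrip:
    def test_noiseless_inversion_recovers_coefficients(
        self, apple_map_64, reference_64
    ):
        opmap, _, _ = apple_map_64
        stack = synth.render_stack(opmap)
        rd_dc, rd_ac = synth.demodulate_scene(stack, reference_64)
        est = invert.invert_map(
            rd_dc.Rd, rd_ac.Rd, pixel_size=opmap.pixel_size, method="nls"
        )
        nmae_a = np.abs(est.mu_a - opmap.mu_a).sum() / opmap.mu_a.sum()
        nmae_s = np.abs(est.mu_s_prime - opmap.mu_s_prime).sum() / opmap.mu_s_prime.sum()
        assert nmae_a <= 0.01
        assert nmae_s <= 0.01


class TestBuildDataset:
    def test_small_sweep_split_ratio(self, tmp_path):
        sweep = {"mu_a": [0.05, 0.1, 0.2, 0.3, 0.4],
                 "mu_s_prime": [1.0, 2.0, 3.0], "severity": [0.0]}
        manifest = synth.build_dataset(tmp_path, seed=1, sweep=sweep, size=32)
        assert len(manifest.entries) == 15
        # round(0.7 * 15) = 10 train, 5 validation
        assert len(manifest.paths("train")) == 10
        assert len(manifest.paths("val")) == 5

    def test_bit_reproducible_under_seed(self, tmp_path):
        import tifffile

        sweep = {"mu_a": [0.1], "mu_s_prime": [1.5, 2.5], "severity": [0.0, 1.0]}
        m1 = synth.build_dataset(tmp_path / "a", seed=3, sweep=sweep, size=32)
        m2 = synth.build_dataset(tmp_path / "b", seed=3, sweep=sweep, size=32)
        assert [e["split"] for e in m1.entries] == [e["split"] for e in m2.entries]
        for e1, e2 in zip(m1.entries, m2.entries):
            a = tifffile.imread(tmp_path / "a" / e1["input"])
            b = tifffile.imread(tmp_path / "b" / e2["input"])
            np.testing.assert_array_equal(a, b)

    def test_manifest_round_trip(self, tmp_path):
        sweep = {"mu_a": [0.1], "mu_s_prime": [1.5], "severity": [0.0]}
        m = synth.build_dataset(tmp_path, seed=0, sweep=sweep, size=32)
        loaded = synth.DatasetManifest.load(tmp_path / "manifest.json")
        assert loaded.entries == m.entries
        assert loaded.seed == 0


@pytest.fixture(scope="module")
def cap_scene():
    spec = synth.FruitSceneSpec(
        "apple", size=64, surface="spherical_cap", height_max=20.0
    )
    return synth.render_curved_scene(spec)


class TestCurvedScene:
    def test_center_pixel_undistorted(self, cap_scene):
        c = cap_scene.c_field
        r, cc = np.unravel_index(np.argmax(cap_scene.height), c.shape)
        assert c[r, cc] == 1.0
        assert cap_scene.distorted.I_dc[r, cc] == pytest.approx(
            cap_scene.undistorted.I_dc[r, cc]
        )

    def test_exact_inversion_of_injected_distortion(self, cap_scene):
        from sfdibruise.profilometry import CorrectionField, correct_reflectance

        cf = CorrectionField(c=cap_scene.c_field,
                             low_confidence=cap_scene.c_field <= synth.C_MIN)
        rec = correct_reflectance(cap_scene.distorted.I_dc, cf)
        np.testing.assert_allclose(rec, cap_scene.undistorted.I_dc, rtol=1e-12)

    def test_planar_surface_rejected(self):
        with pytest.raises(ValueError):
            synth.render_curved_scene(synth.FruitSceneSpec("apple", size=32))
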