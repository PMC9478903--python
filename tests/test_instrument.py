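"""Phantom scenes and the bucket-detector forward model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fsikit.instrument import (
    DepthPhantomConfig,
    DilutionPhantomConfig,
    NoiseModel,
    Scene,
    WirePhantomConfig,
    acquire,
    depth_attenuation_factor,
    depth_masks,
    dilution_layout,
    effective_attenuation,
    make_depth_scene,
    make_dilution_scene,
    make_wire_scene,
    measure,
    smooth_phantom_suite,
)
from fsikit.patterns import circular_sampling_plan, fourier_pattern, PHASES


class TestWirePhantom:
    def test_zero_optical_depth_is_uniform_background(self):
        cfg = WirePhantomConfig(optical_depth=0.0, background=0.7)
        scene = make_wire_scene(cfg, (32, 40), 0.52)
        assert np.allclose(scene.intensity, 0.7, atol=1e-12)

    def test_center_transmission_follows_beer_lambert(self):
        # a wide wire sampled at its center chord: exp(-ln 2) halves the field
        cfg = WirePhantomConfig(diameter_mm=10.0, optical_depth=math.log(2.0),
                                background=1.0)
        scene = make_wire_scene(cfg, (33, 41), 0.52)
        center = scene.intensity[16, 20]
        assert center == pytest.approx(0.5, rel=1e-3)

    @staticmethod
    def _supersampled_absorption(cfg, pitch, M, f):
        """Box-averaged f-x supersampled rendering of the same wire profile."""
        rows = (np.arange(M * f) + 0.5) / f - 0.5
        cr = (M - 1) / 2.0
        R = 0.5 * cfg.diameter_mm / pitch
        frac = np.clip(1.0 - ((rows - cr) / R) ** 2, 0.0, None)
        tx = np.exp(-cfg.optical_depth * np.sqrt(frac))
        return (1.0 - tx.reshape(M, f).mean(axis=1)).sum()

    def test_matches_10x_supersampling_oracle_within_1pct(self):
        cfg = WirePhantomConfig(diameter_mm=2.0, optical_depth=2.0, background=1.0)
        pitch = 0.52
        M, N = 24, 16
        scene = make_wire_scene(cfg, (M, N), pitch)
        absorbed = (1.0 - scene.intensity[:, N // 2]).sum()
        assert absorbed == pytest.approx(
            self._supersampled_absorption(cfg, pitch, M, 10), rel=0.01)

    def test_subpixel_wire_matches_fine_reference_within_1pct(self):
        # the 0.4-mm wire spans < 1 pixel; check against a 1000x reference
        cfg = WirePhantomConfig(diameter_mm=0.4, optical_depth=2.0, background=1.0)
        pitch = 0.52
        M, N = 24, 16
        scene = make_wire_scene(cfg, (M, N), pitch)
        absorbed = (1.0 - scene.intensity[:, N // 2]).sum()
        assert absorbed == pytest.approx(
            self._supersampled_absorption(cfg, pitch, M, 1000), rel=0.01)

    def test_wire_outside_field_warns_and_renders_background(self):
        cfg = WirePhantomConfig(center_px=(-50.0, 20.0), background=0.9)
        with pytest.warns(UserWarning):
            scene = make_wire_scene(cfg, (16, 16), 0.52)
        assert np.allclose(scene.intensity, 0.9)

    def test_modality_tag(self):
        assert make_wire_scene(WirePhantomConfig(), (16, 16)).modality == "xray"


class TestDilutionPhantom:
    def test_all_zero_concentrations_give_zero_scene(self):
        cfg = DilutionPhantomConfig(concentrations=(0.0, 0.0, 0.0),
                                    well_radius_px=3.0)
        scene = make_dilution_scene(cfg, (32, 64))
        assert np.all(scene.intensity == 0.0)

    def test_well_plateau_equals_gain_times_concentration(self):
        cfg = DilutionPhantomConfig(concentrations=(11.86, 0.0), gain=1.0,
                                    well_radius_px=6.0)
        scene = make_dilution_scene(cfg, (48, 64))
        placed = dilution_layout(cfg, (48, 64))
        (r, c), conc = placed[-1]  # rightmost = highest concentration
        assert conc == 11.86
        assert scene.intensity[int(r), int(c)] == pytest.approx(11.86)

    def test_serial_dilution_ratio_is_two(self):
        cfg = DilutionPhantomConfig()
        placed = dilution_layout(cfg, (96, 128))
        concs = [c for _, c in placed if c > 0]
        # the printed concentrations are rounded to 0.01, so successive
        # ratios match 2.0 only to that precision
        for lo, hi in zip(concs, concs[1:]):
            assert hi / lo == pytest.approx(2.0, rel=7e-3)

    def test_water_leftmost_layout(self):
        placed = dilution_layout(DilutionPhantomConfig(), (96, 128))
        concs = [c for _, c in placed]
        assert concs[0] == 0.0
        assert concs == sorted(concs)

    def test_overlapping_wells_rejected(self):
        cfg = DilutionPhantomConfig(
            concentrations=(1.0, 2.0),
            centers_px=((16.0, 20.0), (16.0, 25.0)),
            well_radius_px=6.0,
        )
        with pytest.raises(ValueError, match="overlap"):
            make_dilution_scene(cfg, (32, 64))

    def test_well_outside_field_rejected(self):
        cfg = DilutionPhantomConfig(concentrations=(1.0,),
                                    centers_px=((2.0, 2.0),), well_radius_px=6.0)
        with pytest.raises(ValueError, match="fit"):
            make_dilution_scene(cfg, (32, 64))


class TestDepthPhantom:
    def test_zero_depth_has_unit_attenuation(self):
        cfg = DepthPhantomConfig(depth_mm=0.0)
        assert depth_attenuation_factor(cfg) == 1.0

    def test_mu_eff_matches_hand_calculation(self):
        # sqrt(3 * 0.03 * (0.03 + 12.3)) evaluated independently
        assert effective_attenuation(0.03, 12.3) == pytest.approx(
            1.0534229919647662, abs=1e-12
        )

    def test_attenuation_strictly_decreasing_in_depth(self):
        factors = [depth_attenuation_factor(DepthPhantomConfig(depth_mm=d))
                   for d in (0, 2, 4, 6, 8)]
        assert all(a > b for a, b in zip(factors, factors[1:]))

    def test_stripe_amplitude_and_blur_conservation(self):
        # center the stripe on a pixel row so at least one row is fully covered
        cfg = DepthPhantomConfig(depth_mm=4.0, emission=2.0, scatter_blur=False,
                                 center_row=47.0)
        scene = make_depth_scene(cfg, (96, 128), 0.52)
        expected = 2.0 * depth_attenuation_factor(cfg)
        assert scene.intensity.max() == pytest.approx(expected, rel=1e-9)
        blurred = make_depth_scene(
            DepthPhantomConfig(depth_mm=4.0, emission=2.0, scatter_blur=True,
                               center_row=47.0), (96, 128), 0.52)
        # lateral diffusion spreads but conserves the emitted flux
        assert blurred.intensity.sum() == pytest.approx(scene.intensity.sum(),
                                                        rel=1e-3)
        assert blurred.intensity.max() < scene.intensity.max()

    def test_masks_disjoint_and_guarded(self):
        cfg = DepthPhantomConfig(depth_mm=6.0)
        tube, bg = depth_masks(cfg, (96, 128), 0.52)
        assert not np.any(tube & bg)
        assert tube.any() and bg.any()


class TestMeasure:
    def test_zero_scene_zero_noise(self):
        scene = Scene(np.zeros((6, 8)))
        pat = fourier_pattern(1, 2, (6, 8), 0.0)
        assert measure(scene, pat) == 0.0

    def test_uniform_scene_linearity_in_pattern_sum(self):
        scene = Scene(np.full((6, 8), 3.0))
        pat = fourier_pattern(2, 1, (6, 8), PHASES[1])
        assert measure(scene, pat) == pytest.approx(3.0 * pat.sum(), rel=1e-12)

    def test_matches_double_loop_sum(self, rng, small_scene):
        pat = rng.random((6, 8))
        expected = sum(
            small_scene.intensity[x, y] * pat[x, y]
            for x in range(6) for y in range(8)
        )
        assert measure(small_scene, pat) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self, small_scene):
        with pytest.raises(ValueError):
            measure(small_scene, np.ones((4, 4)))

    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_linear_in_scene_at_zero_noise(self, a, b):
        r = np.random.default_rng(0)
        i1, i2 = r.random((5, 5)), r.random((5, 5))
        pat = r.random((5, 5))
        combo = np.clip(a * i1 + b * i2, 0, None)
        # restrict to nonnegative combinations to satisfy the scene contract
        if np.any(a * i1 + b * i2 < 0):
            return
        lhs = measure(Scene(combo), pat)
        rhs = a * measure(Scene(i1), pat) + b * measure(Scene(i2), pat)
        assert lhs == pytest.approx(rhs, abs=1e-9 * max(1.0, abs(rhs)))


class TestAcquire:
    def test_three_responses_per_coefficient(self, small_scene):
        plan = circular_sampling_plan((6, 8), 0.5)
        ms = acquire(small_scene, plan, use_binary=False)
        assert len(ms) == 3 * len(plan)

    def test_zero_noise_grayscale_reproduces_measure(self, small_scene):
        plan = circular_sampling_plan((6, 8), 0.3)
        ms = acquire(small_scene, plan, use_binary=False)
        for u, v, p, d in zip(ms.u, ms.v, ms.phase_index, ms.D):
            pat = fourier_pattern(u, v, (6, 8), PHASES[p])
            assert d == pytest.approx(measure(small_scene, pat), rel=1e-12)

    def test_fixed_seed_is_bit_identical(self, small_scene):
        plan = circular_sampling_plan((6, 8), 1.0)
        noise = NoiseModel(gaussian_sigma=0.3, ambient_offset=2.0, seed=99)
        a = acquire(small_scene, plan, use_binary=True, noise=noise)
        b = acquire(small_scene, plan, use_binary=True, noise=noise)
        assert np.array_equal(a.D, b.D)

    def test_metadata_records_acquisition(self, small_scene):
        plan = circular_sampling_plan((6, 8), 0.5)
        noise = NoiseModel(gaussian_sigma=0.1, seed=5)
        ms = acquire(small_scene, plan, use_binary=True, noise=noise)
        assert ms.metadata["shape"] == [6, 8]
        assert ms.metadata["binary"] is True
        assert ms.metadata["seed"] == 5
        assert ms.metadata["strategy"] == "circular"

    def test_csv_round_trip(self, tmp_path, small_scene):
        plan = circular_sampling_plan((6, 8), 0.5)
        ms = acquire(small_scene, plan, use_binary=False,
                     noise=NoiseModel(gaussian_sigma=0.05, seed=3))
        path = tmp_path / "m.csv"
        ms.to_csv(path)
        back = type(ms).from_csv(path)
        assert np.allclose(back.D, ms.D)
        assert back.metadata == ms.metadata

    def test_incomplete_triplet_detected(self, small_scene):
        plan = circular_sampling_plan((6, 8), 0.3)
        ms = acquire(small_scene, plan, use_binary=False)
        broken = type(ms)(u=ms.u[:-1], v=ms.v[:-1],
                          phase_index=ms.phase_index[:-1], D=ms.D[:-1],
                          metadata=ms.metadata)
        with pytest.raises(ValueError, match="missing phase"):
            list(broken.triplets())


class TestSceneIO:
    def test_tiff_round_trip(self, tmp_path, rng):
        scene = Scene(rng.random((12, 16)) * 7.3, pitch_mm=0.52, modality="xray")
        scene.to_tiff(tmp_path / "s.tiff")
        back = Scene.from_tiff(tmp_path / "s.tiff")
        assert back.modality == "xray"
        assert back.pitch_mm == 0.52
        assert np.allclose(back.intensity, scene.intensity, atol=2e-4 * 7.3)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Scene(np.array([[-1.0, 0.0]]))


def test_smooth_suite_is_deterministic_and_bounded():
    a = smooth_phantom_suite(n=3)
    b = smooth_phantom_suite(n=3)
    for s1, s2 in zip(a, b):
        assert np.array_equal(s1.intensity, s2.intensity)
        assert s1.intensity.min() >= 0.0 and s1.intensity.max() <= 1.0
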