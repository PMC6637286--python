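"""Phantom generators: determinism, ground-truth completeness, calibration."""

import numpy as np
import pytest

from bpdph.phantoms import (
    ConditionProfile,
    DopplerProfile,
    generate_angiogram_sequence,
    generate_ct_table,
    generate_doppler_trace,
    generate_histology_image,
    generate_pcls_timelapse,
    generate_vascular_volume,
)
from bpdph.phantoms.vascular import PlacementError
from bpdph.pcls import FourPLParams, four_pl_area_percent
from bpdph.profiles import microct_conditions


class TestVascularVolume:
    def test_single_tube_case(self, single_tube):
        vol, gt = single_tube
        assert len(gt.segments) == 1
        assert gt.total_count.tolist() == [1]
        assert 10.0 <= gt.segments[0].diameter_um < 12.0
        assert vol.voxels.max() > 150  # a bright tube exists

    def test_determinism(self):
        p = ConditionProfile("d", [4, 5, 7], [3, 2])
        v1, g1 = generate_vascular_volume(p, shape=(48, 48, 48), seed=11)
        v2, g2 = generate_vascular_volume(p, shape=(48, 48, 48), seed=11)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        assert len(g1.segments) == len(g2.segments)

    def test_different_seeds_differ(self):
        p = ConditionProfile("d", [4, 5, 7], [3, 2])
        v1, _ = generate_vascular_volume(p, shape=(48, 48, 48), seed=1)
        v2, _ = generate_vascular_volume(p, shape=(48, 48, 48), seed=2)
        assert not np.array_equal(v1.voxels, v2.voxels)

    def test_ground_truth_matches_rendered_content(self):
        """Nothing is emplaced beyond the ground truth: with no noise the
        foreground voxel count is explained by the listed segments."""
        p = ConditionProfile("g", [6, 8], [4])
        vol, gt = generate_vascular_volume(
            p, shape=(64, 64, 64), seed=3, poisson_counts=False, noise_sd=0.0
        )
        integral = (vol.voxels.astype(float) - 20.0).clip(0).sum() / 200.0
        assert len(gt.segments) == 4
        # opacity conservation: each tube contributes ~pi r^2 L
        expect = sum(
            np.pi * (s.radius_um / 6.0) ** 2 * np.linalg.norm(s.end - s.start)
            for s in gt.segments
        )
        assert integral == pytest.approx(expect, rel=0.3)

    def test_poisson_calibration_over_seeds(self):
        """Realized per-bin counts average to the expectation (3 SE)."""
        p = ConditionProfile("cal", [4, 5, 7], [8, 5])
        totals = np.zeros(2)
        n = 20
        for seed in range(n):
            _, gt = generate_vascular_volume(p, shape=(72, 72, 72), seed=seed)
            totals += gt.total_count
        means = totals / n
        se = np.sqrt(np.asarray(p.expected_counts) / n)
        assert np.all(np.abs(means - p.expected_counts) <= 3 * se)

    def test_depletion_factor_reflected_in_realized_counts(self):
        """Air vs hyperoxia 4-5 um counts differ by the configured factor
        within Poisson error over 20 seeds (placement-only fast path)."""
        cfg = microct_conditions()
        air = ConditionProfile.from_config(cfg, "air_vehicle")
        hyp = ConditionProfile.from_config(cfg, "hyperoxia_vehicle")
        assert hyp.expected_counts[0] / air.expected_counts[0] == pytest.approx(0.16)
        n = 20
        a = np.zeros(n)
        h = np.zeros(n)
        for seed in range(n):
            _, gta = generate_vascular_volume(air, shape=(128,) * 3, seed=seed, render=False)
            _, gth = generate_vascular_volume(hyp, shape=(128,) * 3, seed=seed + n, render=False)
            a[seed] = gta.total_count[0]
            h[seed] = gth.total_count[0]
        se_a = np.sqrt(air.expected_counts[0] / n)
        se_h = np.sqrt(hyp.expected_counts[0] / n)
        assert abs(a.mean() - air.expected_counts[0]) <= 3 * se_a
        assert abs(h.mean() - hyp.expected_counts[0]) <= 3 * se_h

    def test_too_small_volume_raises_naming_failure(self):
        p = ConditionProfile("big", [20, 30], [1])
        with pytest.raises(PlacementError):
            generate_vascular_volume(p, shape=(8, 8, 8), seed=0)


class TestAngiogram:
    def test_no_background_subtraction_is_exact(self):
        frames, gt = generate_angiogram_sequence(
            (1, 0, 0), n_frames=12, pre_injection_frames=3, seed=0, background=False
        )
        post = frames[-1] - frames[2]
        np.testing.assert_allclose(post, gt.contrast_ramp[-1] * gt.vessel_opacity, atol=1e-9)

    def test_counts_bookkeeping(self):
        _, gt = generate_angiogram_sequence((2, 4, 8), seed=5)
        assert gt.counts == {1: 2, 2: 4, 3: 8}

    def test_pre_frames_are_background_only(self):
        frames, gt = generate_angiogram_sequence((2, 4, 8), seed=1)
        np.testing.assert_array_equal(frames[0], frames[gt.arrival_index - 1])

    def test_zero_generations_rejected(self):
        with pytest.raises(ValueError):
            generate_angiogram_sequence((0, 0, 0))

    def test_salt_noise_registry(self):
        frames, gt = generate_angiogram_sequence(
            (2, 4, 8), seed=2, salt_noise_rate=0.01
        )
        assert len(gt.salt_pixels) > 0
        k, r, c = gt.salt_pixels[0]
        assert frames[k, r, c] == 255.0


class TestPCLS:
    def test_zero_drug_area_equals_bottom(self):
        p = FourPLParams(bottom=100.0, top=57.0, logec50=-8.0, hill=1.0)
        assert four_pl_area_percent(np.array([0.0]), p)[0] == pytest.approx(100.0)

    def test_saturation_approaches_top(self):
        p = FourPLParams(bottom=100.0, top=57.0, logec50=-8.0, hill=1.0)
        assert four_pl_area_percent(np.array([1e-2]), p)[0] == pytest.approx(57.0, abs=1e-3)

    def test_midpoint_identity(self):
        p = FourPLParams(bottom=100.0, top=57.0, logec50=-8.0, hill=1.3)
        assert four_pl_area_percent(np.array([1e-8]), p)[0] == pytest.approx((100 + 57) / 2)

    def test_noise_free_frames_track_target(self):
        p = FourPLParams(bottom=100.0, top=60.0, logec50=-8.0, hill=1.0)
        frames, gt = generate_pcls_timelapse(
            p, [1e-9, 1e-8, 1e-7], frames_per_step=3, noise_sd=0.0, seed=0
        )
        assert np.all(np.abs(gt.mask_area_px - gt.target_area_px) <= 3)

    def test_negative_noise_rejected(self):
        p = FourPLParams(bottom=100.0, top=60.0, logec50=-8.0, hill=1.0)
        with pytest.raises(ValueError):
            generate_pcls_timelapse(p, [1e-9], noise_sd=-0.1)


class TestDoppler:
    def test_construction_contract(self):
        prof = DopplerProfile(tpv=30.0, rvet=100.0, sample_rate=1000.0, heart_period=150.0)
        t, v = generate_doppler_trace(prof)
        assert t[np.argmax(v)] == pytest.approx(30.0)
        nz = np.flatnonzero(v > 0)
        assert t[nz[-1]] <= 100.0
        assert t[nz[-1]] >= 99.0

    def test_symmetric_triangle_peaks_at_midpoint(self):
        prof = DopplerProfile(tpv=50.0, rvet=100.0, sample_rate=1000.0, heart_period=150.0)
        t, v = generate_doppler_trace(prof)
        assert t[np.argmax(v)] == pytest.approx(prof.rvet / 2)

    def test_low_sample_rate_rejected(self):
        prof = DopplerProfile(tpv=16.0, rvet=50.0, sample_rate=500.0, heart_period=120.0)
        with pytest.raises(ValueError):
            generate_doppler_trace(prof)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            DopplerProfile(tpv=60.0, rvet=50.0)


class TestCtTable:
    def test_zero_noise_equals_group_means(self):
        means = {"a": {"Actb": 18.0, "X": 25.0}, "b": {"Actb": 18.0, "X": 24.0}}
        t = generate_ct_table(means, noise_sd=0.0, n_per_group=3)
        assert np.all(t.ct.loc[t.groups == "a", "X"] == 25.0)
        assert np.all(t.ct.loc[t.groups == "b", "Actb"] == 18.0)

    def test_missing_housekeeping_rejected(self):
        with pytest.raises(ValueError):
            generate_ct_table({"a": {"X": 25.0}}, housekeeping="Actb")


class TestHistology:
    def test_zero_collagen(self):
        img, gt = generate_histology_image(0.0, 0.0, shape=(64, 64), seed=0)
        assert gt.collagen_mask.sum() == 0

    def test_exact_fraction(self):
        img, gt = generate_histology_image(0.25, 0.0, shape=(128, 128), seed=1)
        assert gt.collagen_fraction == pytest.approx(0.25, abs=1e-3)

    def test_vessel_exclusion_bookkeeping(self):
        img, gt = generate_histology_image(0.1, 0.1, shape=(128, 128), seed=2)
        assert not np.any(gt.collagen_mask & gt.vessel_mask)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            generate_histology_image(0.9, 0.3)
        with pytest.raises(ValueError):
            generate_histology_image(-0.1)
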