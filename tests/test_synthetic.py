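"""Generator contracts: determinism, noise models, closed-form MSDs."""

import numpy as np
import pytest

from punctakit.msd import average_msd, compute_msd
from punctakit.synthetic import (
    BrownianMotion,
    ConfinedMotion,
    DirectedMotion,
    FixedMotion,
    FrapConfig,
    HoppingMotion,
    SimulationConfig,
    SpotSpec,
    simulate_dual_channel_puncta,
    simulate_frap_series,
    simulate_fusion_standard,
    simulate_nucleus_image,
    simulate_timelapse,
    simulate_trajectories,
)

from conftest import simulate_track_ensemble, trajectories_from_ground_truth


def gaussian_peak(amplitude, x0, y0, sigma_px, row, col):
    return amplitude * np.exp(-((col - x0) ** 2 + (row - y0) ** 2) / (2 * sigma_px**2))


class TestNucleusImage:
    def test_noise_free_empty_image_is_background(self):
        cfg = SimulationConfig(spots=[], read_noise_sd=0.0, photon_scale=None)
        stack, gt = simulate_nucleus_image(cfg)
        img = stack.frame(0)
        nuc = cfg.nucleus.mask(cfg.image_shape)
        assert np.all(img[nuc] == cfg.background_level)
        assert np.all(img[~nuc] == cfg.background_level * cfg.outside_fraction)
        assert len(gt.positions) == 0

    def test_single_spot_peak_matches_direct_gaussian_evaluation(self):
        # oracle: evaluate the Gaussian on the pixel grid directly
        spot = SpotSpec(initial_position=(6.43, 6.41), amplitude=1000.0, psf_sigma=0.15)
        cfg = SimulationConfig(spots=[spot], read_noise_sd=0.0, photon_scale=None)
        stack, _ = simulate_nucleus_image(cfg)
        img = stack.frame(0)
        x0, y0 = 64.3, 64.1  # px
        row, col = 64, 64
        expected = cfg.background_level + gaussian_peak(1000.0, x0, y0, 1.5, row, col)
        assert img[row, col] == pytest.approx(expected, rel=1e-12)

    def test_seed_contract(self):
        spot = SpotSpec(initial_position=(6.4, 6.4))
        base = dict(spots=[spot], read_noise_sd=2.0, photon_scale=1.0)
        a, _ = simulate_nucleus_image(SimulationConfig(**base, seed=1))
        b, _ = simulate_nucleus_image(SimulationConfig(**base, seed=1))
        c, _ = simulate_nucleus_image(SimulationConfig(**base, seed=2))
        np.testing.assert_array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_confined_spot_outside_nucleus_rejected(self):
        spot = SpotSpec(
            initial_position=(0.1, 0.1), motion=ConfinedMotion(sigma_s=0.05, tau=1.0)
        )
        cfg = SimulationConfig(spots=[spot])
        with pytest.raises(ValueError, match="outside the nucleus"):
            simulate_nucleus_image(cfg)

    def test_noise_free_intensity_conservation(self):
        # total intensity = background integral + sum of Gaussian masses on the grid
        spot = SpotSpec(initial_position=(6.4, 6.4), amplitude=500.0, psf_sigma=0.15)
        cfg = SimulationConfig(spots=[spot], read_noise_sd=0.0, photon_scale=None)
        stack, _ = simulate_nucleus_image(cfg)
        empty, _ = simulate_nucleus_image(cfg.model_copy(update={"spots": []}))
        rows, cols = cfg.image_shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        mass = gaussian_peak(500.0, 64.0, 64.0, 1.5, yy, xx).sum()
        assert stack.frames.sum() == pytest.approx(empty.frames.sum() + mass, rel=1e-9)


class TestMotionModel:
    def test_fixed_motion_msd_is_zero(self):
        trajs = simulate_track_ensemble(FixedMotion(), n_tracks=3, seed=0)
        for tr in trajs:
            assert np.allclose(compute_msd(tr).msd_um2, 0.0)

    def test_brownian_ensemble_msd_matches_4dt(self):
        d = 0.01
        trajs = simulate_track_ensemble(BrownianMotion(d=d), n_tracks=500, seed=7)
        avg = average_msd([compute_msd(tr) for tr in trajs])
        for i in [0, 4, 9]:  # lags 0.2, 1.0, 2.0 s
            t = avg.lags_s[i]
            assert abs(avg.msd_um2[i] - 4 * d * t) < 3 * avg.sem_um2[i]

    def test_confined_ensemble_msd_plateau_and_rise(self):
        sigma_s, tau = 0.1, 1.0
        a_true = 4 * sigma_s**2
        trajs = simulate_track_ensemble(ConfinedMotion(sigma_s=sigma_s, tau=tau), 500, seed=8)
        avg = average_msd([compute_msd(tr) for tr in trajs])
        for i in [0, 9, len(avg) - 1]:
            t = avg.lags_s[i]
            expected = a_true * (1 - np.exp(-t / tau))
            assert abs(avg.msd_um2[i] - expected) < 3 * max(avg.sem_um2[i], 1e-4)

    def test_directed_motion_is_deterministic_ballistic(self):
        v = 0.1
        trajs = simulate_track_ensemble(DirectedMotion(v=v, heading=0.7), 1, seed=0)
        curve = compute_msd(trajs[0])
        np.testing.assert_allclose(curve.msd_um2, v**2 * curve.lags_s**2, rtol=1e-10)

    def test_composite_motion_msds_add(self):
        d, sigma_s, tau = 0.005, 0.1, 1.0
        motion = [BrownianMotion(d=d), ConfinedMotion(sigma_s=sigma_s, tau=tau)]
        trajs = simulate_track_ensemble(motion, 800, seed=9)
        avg = average_msd([compute_msd(tr) for tr in trajs])
        i = 9  # lag 2 s
        t = avg.lags_s[i]
        expected = 4 * sigma_s**2 * (1 - np.exp(-t / tau)) + 4 * d * t
        assert abs(avg.msd_um2[i] - expected) < 3 * avg.sem_um2[i]

    def test_hopping_motion_plateau_exceeds_pure_confinement(self):
        conf = simulate_track_ensemble(ConfinedMotion(sigma_s=0.1, tau=1.0), 200, seed=3)
        hop = simulate_track_ensemble(
            HoppingMotion(sigma_s=0.1, tau=1.0, hop_rate=0.5, hop_length=0.3), 200, seed=3
        )
        avg_c = average_msd([compute_msd(tr) for tr in conf])
        avg_h = average_msd([compute_msd(tr) for tr in hop])
        assert avg_h.msd_um2[-1] > avg_c.msd_um2[-1]

    def test_tau_zero_with_confinement_rejected(self):
        with pytest.raises(ValueError, match="tau > 0"):
            ConfinedMotion(sigma_s=0.1, tau=0.0)

    def test_timelapse_requires_two_frames(self):
        cfg = SimulationConfig(spots=[], n_frames=1)
        with pytest.raises(ValueError, match="n_frames"):
            simulate_timelapse(cfg)

    def test_timelapse_seed_determinism(self):
        spot = SpotSpec(initial_position=(6.4, 6.4), motion=BrownianMotion(d=0.01))
        cfg = SimulationConfig(spots=[spot], n_frames=5, read_noise_sd=1.0, seed=11)
        s1, g1 = simulate_timelapse(cfg)
        s2, g2 = simulate_timelapse(cfg)
        np.testing.assert_array_equal(s1.frames, s2.frames)
        np.testing.assert_array_equal(
            g1.positions.to_numpy(), g2.positions.to_numpy()
        )


class TestFrapGenerator:
    def test_immobile_series_is_flat_at_bleach_depth(self):
        cfg = FrapConfig(mobile_fraction=0.0)
        series, truth = simulate_frap_series(cfg)
        post = series.roi[series.phase == "post"] - cfg.background
        np.testing.assert_allclose(post, cfg.baseline * cfg.bleach_depth, rtol=1e-12)

    def test_instant_full_recovery_limit(self):
        cfg = FrapConfig(mobile_fraction=1.0, recovery_rate=1e6)
        series, _ = simulate_frap_series(cfg)
        first_post = np.nonzero(series.phase == "post")[0][0]
        assert series.roi[first_post] - cfg.background == pytest.approx(cfg.baseline)

    def test_bleach_depth_bounds(self):
        with pytest.raises(ValueError):
            FrapConfig(bleach_depth=1.5)
        with pytest.raises(ValueError):
            FrapConfig(bleach_depth=0.0)


class TestDualChannel:
    def test_equal_brightness_ratio_is_count_over_three(self):
        pairs, _ = simulate_dual_channel_puncta(5, 9, 10.0, 10.0, 0.0, seed=0)
        np.testing.assert_allclose(pairs["i_red"] / pairs["i_green"], 3.0)

    def test_zero_count_gives_zero_red(self):
        pairs, _ = simulate_dual_channel_puncta(5, 0, 10.0, 10.0, 0.1, seed=0)
        np.testing.assert_allclose(pairs["i_red"], 0.0)

    def test_negative_noise_cv_rejected(self):
        with pytest.raises(ValueError, match="noise_cv"):
            simulate_dual_channel_puncta(5, 9, 10.0, 10.0, -0.1, seed=0)
        with pytest.raises(ValueError, match="noise_cv"):
            simulate_fusion_standard(5, 10.0, 10.0, -0.1, seed=0)


def test_config_rejects_nucleus_outside_image():
    with pytest.raises(ValueError, match="nucleus"):
        SimulationConfig(
            image_shape=(64, 64),
            nucleus={"center": (32, 32), "semi_axes": (40, 10)},
        )
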