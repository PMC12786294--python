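"""MSD computation against brute force and motion-model fitting."""

import numpy as np
import pytest

from punctakit.msd import (
    ConfinedDiffusionModel,
    MSDCurve,
    average_msd,
    compute_msd,
    fit_msd_model,
    msd_model,
)
from punctakit.tracking import Trajectory

from conftest import make_trajectory


def brute_force_msd(traj: Trajectory, max_lag: int):
    """O(n^2) oracle: mean squared displacement over all pairs per lag."""
    frames = np.asarray(traj.frames)
    pos = traj.positions()
    dt = (traj.times[1] - traj.times[0]) / (frames[1] - frames[0])
    out = {}
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            lag = frames[j] - frames[i]
            if lag <= max_lag:
                d = pos[j] - pos[i]
                out.setdefault(lag, []).append(float(d @ d))
    lags = sorted(out)
    return (
        np.array([l * dt for l in lags]),
        np.array([np.mean(out[l]) for l in lags]),
        np.array([len(out[l]) for l in lags]),
    )


class TestComputeMsd:
    def test_hand_computed_straight_line(self):
        tr = make_trajectory([(0, 0), (1, 0), (2, 0)], dt=0.2)
        curve = compute_msd(tr)
        np.testing.assert_allclose(curve.lags_s, [0.2, 0.4])
        np.testing.assert_allclose(curve.msd_um2, [1.0, 4.0])
        np.testing.assert_array_equal(curve.n_pairs, [2, 1])

    def test_stationary_track_all_zero(self):
        tr = make_trajectory([(3, 3)] * 10)
        assert np.all(compute_msd(tr).msd_um2 == 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        tr = make_trajectory(rng.normal(0, 0.5, size=(30, 2)))
        curve = compute_msd(tr)
        lags, msds, counts = brute_force_msd(tr, 29)
        np.testing.assert_allclose(curve.lags_s, lags, rtol=1e-12)
        np.testing.assert_allclose(curve.msd_um2, msds, rtol=1e-12)
        np.testing.assert_array_equal(curve.n_pairs, counts)

    def test_pairs_spanning_bridged_gap_excluded(self):
        tr = Trajectory(track_id=0)
        for f in [0, 1, 2, 5, 6]:  # frames 3-4 missing
            tr.append(f, 0.2 * f, float(f), 0.0, gap=(f == 5))
        curve = compute_msd(tr)
        # lag 1: pairs (0,1),(1,2),(5,6) — (2,5) spans the gap at lag 3
        assert curve.n_pairs[list(curve.lags_s).index(pytest.approx(0.2))] == 3
        assert not np.any(np.isclose(curve.lags_s, 3 * 0.2)) or (
            curve.n_pairs[np.argmin(np.abs(curve.lags_s - 0.6))] == 0
        )

    def test_overlong_max_lag_truncates_with_warning(self):
        tr = make_trajectory([(0, 0), (1, 0), (2, 0)])
        with pytest.warns(UserWarning, match="truncating"):
            curve = compute_msd(tr, max_lag_frames=10)
        assert len(curve) == 2

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(make_trajectory([(0, 0)]))


class TestAverageMsd:
    def test_identical_curves_mean_equals_curve_sem_zero(self):
        tr = make_trajectory([(0, 0), (1, 0), (2, 0)])
        c = compute_msd(tr)
        avg = average_msd([c, c, c])
        np.testing.assert_allclose(avg.msd_um2, c.msd_um2)
        np.testing.assert_allclose(avg.sem_um2, 0.0)

    def test_unequal_lengths_long_lags_averaged_over_fewer_tracks(self):
        long = make_trajectory([(0, 0), (1, 0), (2, 0), (3, 0)])
        short = make_trajectory([(0, 0), (1, 0)])
        avg = average_msd([compute_msd(long), compute_msd(short)])
        assert avg.n_tracks[0] == 2
        assert avg.n_tracks[-1] == 1


class TestModelFit:
    def test_noise_free_confined_curve_recovered_within_one_percent(self):
        a, tau = 0.04, 10.0
        t = np.arange(1, 201) * 0.2
        curve = MSDCurve(t, msd_model(t, a, tau, 0.0, 0.0), np.arange(200, 0, -1))
        fit = fit_msd_model(curve, fit_fraction=1.0)
        assert fit.a == pytest.approx(a, rel=0.01)
        assert fit.tau == pytest.approx(tau, rel=0.01)
        assert fit.d_eff == pytest.approx(a / (4 * tau), rel=0.01)

    def test_pure_ballistic_curve_recovers_velocity(self):
        v = 0.1
        t = np.arange(1, 41) * 0.2
        curve = MSDCurve(t, v**2 * t**2, np.arange(40, 0, -1))
        fit = fit_msd_model(curve, fit_fraction=1.0)
        assert fit.v == pytest.approx(v, rel=0.01)
        # non-ballistic terms contribute negligibly over the fitted range
        t_max = t[-1]
        other = fit.a * (1 - np.exp(-t_max / fit.tau)) + 4 * fit.linear_d * t_max
        assert other < 1e-4 * v**2 * t_max**2

    def test_d_eff_identity_holds_exactly(self):
        t = np.arange(1, 41) * 0.2
        curve = MSDCurve(t, msd_model(t, 0.05, 2.0, 1e-4, 0.0), np.arange(40, 0, -1))
        fit = fit_msd_model(curve, fit_fraction=1.0)
        assert fit.d_eff == fit.a / (4 * fit.tau)

    def test_residual_non_increasing_on_nested_fit_range(self):
        a, tau = 0.04, 2.0
        t = np.arange(1, 81) * 0.2
        curve = MSDCurve(t, msd_model(t, a, tau, 0.0, 0.0), np.arange(80, 0, -1))
        rss_half = fit_msd_model(curve, fit_fraction=0.5).rss
        rss_full = fit_msd_model(curve, fit_fraction=1.0).rss
        assert rss_half <= rss_full + 1e-15

    def test_summary_mentions_all_parameters(self):
        t = np.arange(1, 21) * 0.2
        curve = MSDCurve(t, msd_model(t, 0.04, 1.0, 0.0, 0.0), np.arange(20, 0, -1))
        s = ConfinedDiffusionModel(curve, fit_fraction=1.0).fit().summary()
        for token in ["A (confinement", "tau", "D_eff", "linear D", "v (transport"]:
            assert token in s

    def test_too_few_lags_rejected(self):
        curve = MSDCurve([0.2, 0.4, 0.6], [1, 2, 3], [3, 2, 1])
        with pytest.raises(ValueError, match="4 usable lags"):
            fit_msd_model(curve)


class TestCurveValidation:
    def test_non_ascending_lags_rejected(self):
        with pytest.raises(ValueError):
            MSDCurve([0.4, 0.2], [1, 2], [1, 1])

    def test_negative_msd_rejected(self):
        with pytest.raises(ValueError):
            MSDCurve([0.2, 0.4], [1, -2], [1, 1])
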