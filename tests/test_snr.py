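"""SNR statistic invariances, background sampling, profiles, percent change."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punctakit.io import CircleRoi, PolylineRoi
from punctakit.snr import line_profile, measure_snr, ros_percent_change, snr_cohort_summary
from punctakit.synthetic import SimulationConfig, SpotSpec, simulate_nucleus_image


@pytest.fixture
def scene(rng):
    img = rng.normal(100.0, 10.0, size=(128, 128))
    cx = cy = 64
    yy, xx = np.mgrid[0:128, 0:128]
    img += 1000.0 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 2.0**2))
    nucleus = CircleRoi((64, 64), 55).mask((128, 128))
    spot = CircleRoi((64, 64), 5).mask((128, 128))
    exclusion = CircleRoi((64, 64), 10).mask((128, 128))
    return img, spot, nucleus, exclusion


class TestMeasureSnr:
    def test_matches_direct_formula(self, scene):
        img, spot, nucleus, exclusion = scene
        res = measure_snr(img, spot, nucleus, [exclusion], 10, 4.0, seed=1)
        assert res.snr == res.p_signal / res.background_sd
        assert res.p_signal == pytest.approx(
            img[spot].max() - res.background_mean, rel=1e-12
        )
        # background statistics should approximate the generator's N(100, 10)
        assert abs(res.background_mean - 100.0) < 5.0
        assert abs(res.background_sd - 10.0) < 3.0

    @given(gain=st.floats(0.1, 50.0), offset=st.floats(-50.0, 500.0))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, gain, offset):
        rng = np.random.default_rng(99)
        img = rng.normal(100.0, 10.0, size=(96, 96))
        img[44:52, 44:52] += 900.0
        nucleus = CircleRoi((48, 48), 42).mask((96, 96))
        spot = CircleRoi((48, 48), 5).mask((96, 96))
        exclusion = CircleRoi((48, 48), 10).mask((96, 96))
        a = measure_snr(img, spot, nucleus, [exclusion], 8, 4.0, seed=2)
        b = measure_snr(gain * img + offset, spot, nucleus, [exclusion], 8, 4.0, seed=2)
        assert b.snr == pytest.approx(a.snr, rel=1e-9)

    def test_seed_determinism(self, scene):
        img, spot, nucleus, exclusion = scene
        a = measure_snr(img, spot, nucleus, [exclusion], 10, 4.0, seed=7)
        b = measure_snr(img, spot, nucleus, [exclusion], 10, 4.0, seed=7)
        c = measure_snr(img, spot, nucleus, [exclusion], 10, 4.0, seed=8)
        assert (a.background_mean, a.background_sd, a.snr) == (
            b.background_mean,
            b.background_sd,
            b.snr,
        )
        assert a.background_mean != c.background_mean

    def test_flat_background_undefined_snr(self):
        img = np.full((64, 64), 100.0)
        img[30:34, 30:34] = 500.0
        nucleus = CircleRoi((32, 32), 28).mask((64, 64))
        spot = CircleRoi((32, 32), 4).mask((64, 64))
        with pytest.raises(ValueError, match="flat background"):
            measure_snr(img, spot, nucleus, [spot], 5, 3.0, seed=0)

    def test_impossible_placement_reports_helpfully(self):
        img = np.zeros((32, 32))
        nucleus = CircleRoi((16, 16), 5).mask((32, 32))
        spot = CircleRoi((16, 16), 4).mask((32, 32))
        with pytest.raises(ValueError, match="circle"):
            measure_snr(img, spot, nucleus, [spot], 10, 4.0, seed=0)

    def test_generator_round_trip_snr_scale(self):
        # synthetic punctum of known amplitude over known noise
        spot_spec = SpotSpec(initial_position=(6.4, 6.4), amplitude=800.0)
        cfg = SimulationConfig(
            spots=[spot_spec], read_noise_sd=8.0, photon_scale=None, seed=3
        )
        stack, _ = simulate_nucleus_image(cfg)
        nucleus = cfg.nucleus.mask(cfg.image_shape)
        spot = CircleRoi((64, 64), 5).mask(cfg.image_shape)
        excl = CircleRoi((64, 64), 12).mask(cfg.image_shape)
        res = measure_snr(stack.frame(0), spot, nucleus, [excl], 12, 4.0, seed=4)
        # expected SNR ~ amplitude / read-noise SD = 100, within sampling slack
        assert res.snr == pytest.approx(800.0 / 8.0, rel=0.15)

    def test_cohort_summary_mean_sd(self):
        class R:
            def __init__(self, snr):
                self.snr = snr

        mean, sd = snr_cohort_summary([R(10.0), R(20.0), R(30.0)])
        assert mean == pytest.approx(20.0)
        assert sd == pytest.approx(10.0)


class TestLineProfile:
    def test_peak_at_ridge_crossing(self):
        yy, xx = np.mgrid[0:64, 0:64]
        ridge = np.exp(-((xx - 30) ** 2) / (2 * 3.0**2))  # vertical ridge at x=30
        prof = line_profile(ridge, PolylineRoi([(10, 32), (50, 32)]), normalize=True)
        peak_d = prof["distance_px"][prof["intensity"].idxmax()]
        assert peak_d == pytest.approx(20.0, abs=1.0)  # 30 - 10
        assert prof["intensity"].max() == pytest.approx(1.0)

    def test_constant_image_normalizes_to_one(self):
        prof = line_profile(np.full((32, 32), 7.0), PolylineRoi([(2, 2), (29, 29)]))
        np.testing.assert_allclose(prof["intensity"], 1.0)

    def test_two_channels_share_sampling(self):
        imgs = {"red": np.random.default_rng(0).random((32, 32)), "green": np.ones((32, 32))}
        prof = line_profile(imgs, PolylineRoi([(1, 1), (30, 20)]))
        assert len(prof["red"]) == len(prof["green"])

    def test_polyline_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            line_profile(np.zeros((16, 16)), PolylineRoi([(0, 0), (40, 40)]))


class TestRosPercentChange:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([100, 110, 120], [0, 10, 20]),
            ([5, 5, 5], [0, 0, 0]),
            ([100, 95], [0, -5]),
        ],
        ids=["increase", "constant", "decrease"],
    )
    def test_percent_change(self, series, expected):
        np.testing.assert_allclose(ros_percent_change(series), expected)

    def test_zero_first_frame_rejected(self):
        with pytest.raises(ValueError, match="first-frame"):
            ros_percent_change([0, 10])
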