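import math

import numpy as np
import pytest

from gazeqc import (AngularPosition, DataQualityWarning, PrecisionParams,
                    accuracy, bcea, rms_s2s, rms_s2s_sliding_window, std)

from conftest import make_segment

ORIGIN = AngularPosition(0.0, 0.0)


def brute_force_offset(gaze_azi, gaze_ele, tgt_azi, tgt_ele):
    """Independent oracle: explicit 3-vector construction + arccos.

    Built from math-module scalar trigonometry so it shares no code with the
    implementation under test.
    """
    def vec(a, e):
        a, e = math.radians(a), math.radians(e)
        return (math.cos(e) * math.sin(a), math.sin(e),
                math.cos(e) * math.cos(a))

    g, t = vec(gaze_azi, gaze_ele), vec(tgt_azi, tgt_ele)
    dot = sum(gi * ti for gi, ti in zip(g, t))
    return math.degrees(math.acos(max(-1.0, min(1.0, dot))))


class TestAccuracy:
    def test_constant_offset_along_azimuth(self):
        seg = make_segment([0.5] * 10, [0.0] * 10)
        assert accuracy(seg, ORIGIN) == pytest.approx(0.5, abs=1e-9)

    def test_gaze_on_target_gives_zero(self):
        seg = make_segment([3.0] * 5, [-2.0] * 5)
        assert accuracy(seg, AngularPosition(3.0, -2.0)) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_alternation_cancels_under_mean(self):
        seg = make_segment([1.0, -1.0] * 20, [0.0] * 40)
        assert accuracy(seg, ORIGIN) == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_offset_matches_brute_force_oracle(self):
        seg = make_segment([2.0] * 8, [2.0] * 8)
        expected = brute_force_offset(2.0, 2.0, 0.0, 0.0)
        assert expected == pytest.approx(2.83, abs=0.01)  # ~2.83 deg, not 2*sqrt(2)
        assert accuracy(seg, ORIGIN) == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_sample_order(self, rng):
        azi, ele = rng.normal(1, 0.3, 100), rng.normal(-0.5, 0.3, 100)
        perm = rng.permutation(100)
        a = accuracy(make_segment(azi, ele), ORIGIN)
        b = accuracy(make_segment(azi[perm], ele[perm]), ORIGIN)
        assert a == pytest.approx(b, abs=1e-12)

    def test_median_central_tendency_resists_outlier(self):
        azi = np.array([1.0] * 99 + [41.0])
        seg = make_segment(azi, np.zeros_like(azi))
        med = accuracy(seg, ORIGIN, PrecisionParams(central_tendency="median"))
        assert med == pytest.approx(1.0, abs=1e-6)
        assert accuracy(seg, ORIGIN) > med  # mean is dragged by the outlier

    def test_nan_samples_are_ignored(self):
        seg = make_segment([0.5, np.nan, 0.5], [0.0, 0.0, np.nan])
        assert accuracy(seg, ORIGIN) == pytest.approx(0.5, abs=1e-9)

    def test_all_invalid_returns_nan_with_warning(self):
        seg = make_segment([np.nan] * 4, [np.nan] * 4)
        with pytest.warns(DataQualityWarning):
            assert math.isnan(accuracy(seg, ORIGIN))


class TestRmsS2S:
    def test_constant_signal_is_zero(self):
        seg = make_segment([1.0] * 50, [2.0] * 50)
        assert rms_s2s(seg) == 0.0
        assert rms_s2s(seg, "median") == 0.0

    def test_single_three_four_five_displacement(self):
        seg = make_segment([0.0, 3.0], [0.0, 4.0])
        assert rms_s2s(seg) == pytest.approx(5.0)

    def test_equal_displacements_for_both_aggregates(self):
        seg = make_segment([0, 1, 0, 1, 0], [0] * 5)
        assert rms_s2s(seg, "mean") == pytest.approx(1.0)
        assert rms_s2s(seg, "median") == pytest.approx(1.0)

    def test_white_noise_gives_two_sigma(self, noise_segment):
        seg, sigma = noise_segment
        # E[(x_{i+1}-x_i)^2] = 2 sigma^2 per axis, two axes -> RMS-S2S = 2 sigma
        assert rms_s2s(seg) == pytest.approx(2 * sigma, rel=0.03)

    def test_pairs_spanning_nan_are_dropped_not_bridged(self):
        # gap removes both adjacent displacements; remaining ones are 1 deg
        seg = make_segment([0, 1, np.nan, 5, 6], [0] * 5)
        assert rms_s2s(seg) == pytest.approx(1.0)

    def test_no_valid_pair_returns_nan_with_warning(self):
        seg = make_segment([1.0, np.nan, 2.0], [0.0, 0.0, 0.0])
        with pytest.warns(DataQualityWarning):
            assert math.isnan(rms_s2s(seg))

    def test_translation_invariance(self, rng):
        azi, ele = rng.normal(0, 0.1, 500), rng.normal(0, 0.1, 500)
        base = rms_s2s(make_segment(azi, ele))
        shifted = rms_s2s(make_segment(azi + 7.3, ele - 2.1))
        assert shifted == pytest.approx(base, abs=1e-9)


class TestSlidingWindowRms:
    def test_constant_signal_is_zero(self):
        seg = make_segment([1.0] * 600, [1.0] * 600)
        assert rms_s2s_sliding_window(seg, PrecisionParams(), 600.0) == 0.0

    def test_agrees_with_global_rms_for_stationary_noise(self, rng):
        azi, ele = rng.normal(0, 0.1, 10_000), rng.normal(0, 0.1, 10_000)
        seg = make_segment(azi, ele)
        windowed = rms_s2s_sliding_window(seg, PrecisionParams(), 600.0)
        assert windowed == pytest.approx(rms_s2s(seg), rel=0.05)

    def test_robust_to_single_spike(self, rng):
        azi = rng.normal(0, 0.05, 3000)
        azi[1500] = 10.0  # single-sample spike
        seg = make_segment(azi, np.zeros_like(azi))
        assert rms_s2s_sliding_window(seg, PrecisionParams(), 600.0) < rms_s2s(seg)

    def test_window_shorter_than_two_samples_is_an_error(self):
        seg = make_segment(np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError, match="at least 2"):
            rms_s2s_sliding_window(seg, PrecisionParams(window_length_ms=2), 600.0)

    def test_all_windows_blinked_returns_nan_with_warning(self):
        azi = np.full(600, np.nan)
        azi[::60] = 1.0  # never 120 consecutive valid samples
        seg = make_segment(azi, np.zeros(600))
        with pytest.warns(DataQualityWarning):
            assert math.isnan(
                rms_s2s_sliding_window(seg, PrecisionParams(), 600.0))


class TestStd:
    def test_constant_signal_is_zero(self):
        assert std(make_segment([2.0] * 10, [3.0] * 10)) == 0.0

    @pytest.mark.parametrize("azi,ele,expected", [
        ([-1.0, 1.0], [0.0, 0.0], 1.0),                 # population STD_x = 1
        ([-1.0, 1.0], [-1.0, 1.0], math.sqrt(2)),
    ])
    def test_population_normalization(self, azi, ele, expected):
        assert std(make_segment(azi, ele)) == pytest.approx(expected)

    def test_white_noise_gives_sigma_root_two(self, noise_segment):
        seg, sigma = noise_segment
        assert std(seg) == pytest.approx(sigma * math.sqrt(2), rel=0.03)

    def test_rms_to_std_ratio_is_root_two_for_white_noise(self, noise_segment):
        seg, _ = noise_segment
        assert rms_s2s(seg) / std(seg) == pytest.approx(math.sqrt(2), rel=0.05)

    def test_translation_invariance(self, rng):
        azi, ele = rng.normal(0, 0.1, 500), rng.normal(0, 0.1, 500)
        assert std(make_segment(azi + 5, ele - 3)) == pytest.approx(
            std(make_segment(azi, ele)), abs=1e-9)


class TestBcea:
    def test_identical_samples_give_zero_area(self):
        with pytest.warns(DataQualityWarning, match="degenerate"):
            res = bcea(make_segment([1.0] * 10, [1.0] * 10))
        assert res.area == 0.0
        assert res.rho == 0.0

    def test_collinear_samples_give_zero_area(self):
        t = np.linspace(0, 1, 50)
        res = bcea(make_segment(t, 2 * t))  # rho = +1 up to rounding
        assert res.area == pytest.approx(0.0, abs=1e-6)
        assert res.rho == pytest.approx(1.0)

    def test_unit_isotropic_cloud_matches_closed_form(self):
        # sigma_x = sigma_y = 1, rho = 0 by symmetric construction
        azi = np.array([1.0, -1.0, 1.0, -1.0])
        ele = np.array([1.0, 1.0, -1.0, -1.0])
        res = bcea(make_segment(azi, ele))
        expected = 2 * (-math.log(1 - 0.68)) * math.pi  # ~7.159 deg^2
        assert expected == pytest.approx(7.1593, abs=1e-4)
        assert res.area == pytest.approx(expected, rel=1e-12)
        assert res.std_x == pytest.approx(1.0)
        assert res.rho == pytest.approx(0.0, abs=1e-12)

    def test_area_consistent_with_axis_radii(self, rng):
        cov = np.array([[0.04, 0.015], [0.015, 0.09]])
        azi, ele = rng.multivariate_normal([0, 0], cov, 5000).T
        res = bcea(make_segment(azi, ele))
        assert res.area == pytest.approx(
            math.pi * res.major_radius * res.minor_radius, rel=1e-9)
        assert res.anisotropy == pytest.approx(
            res.major_radius / res.minor_radius)
        assert res.anisotropy >= 1.0

    def test_ellipse_contains_requested_fraction(self, rng):
        # under a Gaussian model the ellipse holds ~P of the samples
        n = 100_000
        azi, ele = rng.normal(0, 0.3, n), rng.normal(0, 0.3, n)
        res = bcea(make_segment(azi, ele))
        k = -math.log(1 - 0.68)
        zx = (azi - azi.mean()) / res.std_x
        zy = (ele - ele.mean()) / res.std_y
        d2 = (zx ** 2 - 2 * res.rho * zx * zy + zy ** 2) / (1 - res.rho ** 2)
        fraction = np.mean(d2 <= 2 * k)
        assert fraction == pytest.approx(0.68, abs=0.01)

    def test_orientation_tracks_rotation_and_area_is_invariant(self, rng):
        cov = np.array([[0.09, 0.0], [0.0, 0.01]])  # major axis along x
        azi, ele = rng.multivariate_normal([0, 0], cov, 20000).T
        base = bcea(make_segment(azi, ele))
        assert base.orientation == pytest.approx(0.0, abs=2.0)
        theta = math.radians(30)
        rot_azi = azi * math.cos(theta) - ele * math.sin(theta)
        rot_ele = azi * math.sin(theta) + ele * math.cos(theta)
        rotated = bcea(make_segment(rot_azi, rot_ele))
        assert rotated.area == pytest.approx(base.area, rel=1e-6)
        assert rotated.orientation == pytest.approx(30.0, abs=2.0)

    def test_fewer_than_two_valid_samples_is_nan(self):
        with pytest.warns(DataQualityWarning):
            res = bcea(make_segment([1.0, np.nan], [1.0, np.nan]))
        assert math.isnan(res.area)


class TestScalingAndNanInvariants:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scaling_zero_mean_cloud(self, rng, c):
        azi, ele = rng.normal(0, 0.2, 2000), rng.normal(0, 0.2, 2000)
        azi -= azi.mean()
        ele -= ele.mean()
        seg, scaled = make_segment(azi, ele), make_segment(c * azi, c * ele)
        assert std(scaled) == pytest.approx(c * std(seg), rel=1e-9)
        assert rms_s2s(scaled) == pytest.approx(c * rms_s2s(seg), rel=1e-9)
        assert bcea(scaled).area == pytest.approx(c * c * bcea(seg).area,
                                                  rel=1e-9)

    def test_metrics_never_propagate_nan_from_partial_invalidity(self, rng):
        azi, ele = rng.normal(0, 0.1, 1000), rng.normal(0, 0.1, 1000)
        azi[::10] = np.nan
        seg = make_segment(azi, ele)
        assert math.isfinite(accuracy(seg, ORIGIN))
        assert math.isfinite(rms_s2s(seg))
        assert math.isfinite(rms_s2s(seg, "median"))
        assert math.isfinite(std(seg))
        assert math.isfinite(bcea(seg).area)

    def test_nan_only_affects_dropped_samples(self, rng):
        azi, ele = rng.normal(0, 0.1, 500), rng.normal(0, 0.1, 500)
        full_std = std(make_segment(azi, ele))
        azi2, ele2 = azi.copy(), ele.copy()
        azi2[100:110] = np.nan
        kept = np.isfinite(azi2)
        assert std(make_segment(azi2, ele2)) == pytest.approx(
            std(make_segment(azi[kept], ele[kept])), abs=1e-12)
        assert full_std != 0
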