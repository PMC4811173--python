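"""Numeric primitives: normalization, gap filling, filtering, fits, predicates."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import least_squares

from dramatyping.signal_ops import (
    FLAT,
    FALLING,
    RISING,
    InvalidReferenceIntervalError,
    NotEnoughDataError,
    WeightedSeries,
    detect_edge,
    deviates_from_mean,
    fill_gaps,
    fit_and_test,
    gaussian_lowpass,
    is_zigzag,
    normalize_lab_value,
    phase_means_differ,
    remove_outliers,
)

from conftest import make_episode


def series(values, weights=None, start_day=1):
    values = np.asarray(values, dtype=float)
    w = np.ones(len(values)) if weights is None else np.asarray(weights, dtype=float)
    return WeightedSeries(np.arange(start_day, start_day + len(values)), values, w)


class TestNormalize:
    @pytest.mark.parametrize(
        "lv, lo, hi, expected",
        [(10, 10, 50, 0.0), (50, 10, 50, 1.0), (30, 10, 50, 0.5), (70, 10, 50, 1.5)],
    )
    def test_reference_interval_maps_to_unit_interval(self, lv, lo, hi, expected):
        assert normalize_lab_value(lv, lo, hi) == pytest.approx(expected)

    @pytest.mark.parametrize("lo, hi", [(50, 10), (10, 10)])
    def test_degenerate_reference_interval_rejected(self, lo, hi):
        with pytest.raises(InvalidReferenceIntervalError):
            normalize_lab_value(30, lo, hi)


class TestFillGaps:
    def test_contiguous_series_is_identity(self):
        ep = make_episode([1, 2, 3], [0.1, 0.2, 0.3], [2])
        s = fill_gaps(ep)
        assert s.days.tolist() == [1, 2, 3]
        assert s.values.tolist() == [0.1, 0.2, 0.3]
        assert s.weights.tolist() == [1.0, 1.0, 1.0]

    def test_missing_days_filled_with_low_weight_zeros(self):
        ep = make_episode([1, 2, 4], [0.1, 0.2, 0.4], [2])
        s = fill_gaps(ep)
        assert s.days.tolist() == [1, 2, 3, 4]
        assert s.values.tolist() == [0.1, 0.2, 0.0, 0.4]
        assert s.weights.tolist() == [1.0, 1.0, 1e-6, 1.0]

    def test_inserted_day_count_is_span_minus_observed(self):
        ep = make_episode([1, 5], [0.1, 0.5], [3])
        s = fill_gaps(ep)
        assert len(s) == 5
        assert np.count_nonzero(~s.observed_mask) == 3
        assert np.all(s.weights[~s.observed_mask] == 1e-6)

    def test_observed_values_never_change(self):
        ep = make_episode([1, 3, 7, 8], [1.1, -0.4, 2.0, 0.9], [3, 7])
        s = fill_gaps(ep, gap_weight=1e-4)
        observed = {d: v for d, v in ep.observations}
        for d, v, w in zip(s.days, s.values, s.weights):
            if int(d) in observed:
                assert w == 1.0 and v == observed[int(d)]
            else:
                assert w == 1e-4 and v == 0.0


class TestGaussianLowpass:
    def test_constant_series_preserved(self):
        s = gaussian_lowpass(series([0.7] * 9), sigma=1.5)
        assert np.allclose(s.values, 0.7, atol=1e-12)

    def test_impulse_center_matches_truncated_kernel_coefficient(self):
        # independent oracle: normalized Gaussian samples truncated at 4 sigma
        sigma = 1.5
        radius = int(4.0 * sigma + 0.5)
        kernel = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        kernel /= kernel.sum()
        impulse = np.zeros(11)
        impulse[5] = 1.0
        smoothed = gaussian_lowpass(series(impulse), sigma=sigma)
        assert smoothed.values[5] == pytest.approx(kernel[radius], abs=1e-12)
        # and the full interior response is the kernel itself
        assert np.allclose(smoothed.values[5 - 4 : 5 + 5], kernel[radius - 4 : radius + 5], atol=1e-9)

    def test_days_and_weights_unchanged(self, simple_series):
        out = gaussian_lowpass(simple_series, sigma=1.5)
        assert out.days.tolist() == simple_series.days.tolist()
        assert out.weights.tolist() == simple_series.weights.tolist()


class TestRemoveOutliers:
    def test_two_most_deviant_values_replaced_by_median(self):
        s = remove_outliers(series([1, 1, 1, 10, 1, -5, 1]))
        assert s.values.tolist() == [1.0] * 7

    def test_constant_series_unchanged(self):
        s = remove_outliers(series([0.5] * 6))
        assert s.values.tolist() == [0.5] * 6

    def test_tie_broken_by_earliest_day(self):
        # one clear outlier; the "second outlier" is a tie among zeros and the
        # earliest zero is (trivially) replaced by the median 0
        s = remove_outliers(series([0, 0, 0, 0, 5]))
        assert s.values.tolist() == [0.0] * 5

    def test_exactly_two_values_change_and_rest_preserved(self):
        values = [0.2, 0.9, 0.4, 0.5, 3.0, 0.5, -2.0, 0.6]
        out = remove_outliers(series(values))
        changed = [i for i, (a, b) in enumerate(zip(values, out.values)) if a != b]
        assert changed == [4, 6]
        assert [values[i] for i in range(8) if i not in changed] == [
            out.values[i] for i in range(8) if i not in changed
        ]

    def test_gap_fillers_ignored_and_untouched(self):
        s = WeightedSeries(
            np.arange(1, 6),
            np.array([1.0, 0.0, 1.0, 9.0, 1.0]),
            np.array([1.0, 1e-6, 1.0, 1.0, 1.0]),
        )
        out = remove_outliers(s)
        # median of observed values (1,1,9,1) is 1; 9 and earliest 1 replaced
        assert out.values[1] == 0.0  # filler untouched
        assert out.values[3] == 1.0

    def test_needs_three_observed_values(self):
        with pytest.raises(NotEnoughDataError):
            remove_outliers(series([1.0, 2.0]))


class TestFitAndTest:
    def test_constant_input_exact_fit(self):
        r = fit_and_test(series([0.7] * 5), "constant", tol=1e-9)
        assert r.level == pytest.approx(0.7)
        assert r.residual == pytest.approx(0.0, abs=1e-12)
        assert r.within_tolerance

    def test_exact_linear_fit_recovers_slope_and_intercept(self):
        days = np.arange(1, 8)
        r = fit_and_test(series(2 * days + 1), "linear", tol=1e-9)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.residual == pytest.approx(0.0, abs=1e-9)

    def test_step_series_constant_fit_closed_form(self):
        r = fit_and_test(series([0, 0, 1, 1]), "constant", tol=0.4)
        assert r.level == pytest.approx(0.5)
        assert r.residual == pytest.approx(0.5)
        assert not r.within_tolerance

    def test_weighted_fit_matches_levenberg_marquardt(self):
        # the closed-form weighted least-squares solution must agree with an
        # iterative Levenberg-Marquardt optimisation of the same objective
        rng = np.random.default_rng(7)
        days = np.arange(1, 16)
        values = 0.3 * days - 1.0 + rng.normal(0, 0.3, 15)
        weights = np.where(rng.random(15) < 0.3, 1e-6, 1.0)
        s = WeightedSeries(days, values, weights)
        ours = fit_and_test(s, "linear", tol=1.0)
        lm = least_squares(
            lambda p: np.sqrt(weights) * (values - (p[0] * days + p[1])),
            x0=[0.0, 0.0],
            method="lm",
        )
        assert ours.slope == pytest.approx(lm.x[0], abs=1e-8)
        assert ours.intercept == pytest.approx(lm.x[1], abs=1e-8)

    def test_gap_weights_suppress_artificial_zeros(self):
        ep = make_episode([1, 2, 3, 7, 8, 9], [1.0] * 6, [4])
        r = fit_and_test(fill_gaps(ep), "constant", tol=0.01)
        assert r.level == pytest.approx(1.0, abs=1e-4)
        assert r.within_tolerance

    def test_too_few_points_raise(self):
        with pytest.raises(NotEnoughDataError):
            fit_and_test(series([1.0]), "linear", tol=1.0)


class TestPhaseMeansDiffer:
    @pytest.mark.parametrize(
        "pre, later, tol, expected",
        [
            ([1, 1], [1, 1], 0.1, False),
            ([0, 0], [1, 1], 0.5, True),
            ([0, 0], [0.4, 0.4], 0.5, False),
        ],
    )
    def test_mean_difference_thresholding(self, pre, later, tol, expected):
        assert phase_means_differ(pre, later, tol) is expected

    def test_empty_pre_phase_raises(self):
        with pytest.raises(NotEnoughDataError):
            phase_means_differ([], [1.0], 0.1)

    def test_weights_suppress_gap_fillers(self):
        assert not phase_means_differ(
            [1.0, 0.0], [1.0], 0.5, pre_weights=[1.0, 1e-6]
        )


class TestDetectEdge:
    @pytest.mark.parametrize(
        "values, threshold, expected",
        [
            (np.arange(10, dtype=float), 0.1, RISING),
            ([0.5] * 8, 0.1, FLAT),
            (-0.05 * np.arange(10), 0.1, FLAT),
            (-np.arange(10, dtype=float), 0.1, FALLING),
            ([0.3], 0.1, FLAT),  # degenerate phase counts as flat
        ],
    )
    def test_slope_thresholding(self, values, threshold, expected):
        assert detect_edge(values, threshold) == expected

    @given(
        st.lists(st.floats(-3, 3, allow_nan=False), min_size=2, max_size=20),
        st.floats(0.01, 1.0),
    )
    def test_antisymmetry_under_negation(self, values, threshold):
        swap = {RISING: FALLING, FALLING: RISING, FLAT: FLAT}
        assert detect_edge([-v for v in values], threshold) == swap[detect_edge(values, threshold)]


class TestIsZigzag:
    @pytest.mark.parametrize(
        "values, amp, frac, expected",
        [
            ([0, 1, 0, 1, 0, 1], 0.5, 0.8, True),
            (list(range(8)), 0.5, 0.8, False),
            ([0, 1, 2, 3, 2, 3], 0.5, 0.8, False),
            ([0, 1, 0], 0.5, 0.8, False),  # fewer than 4 values
            ([0, 0.1, 0, 0.1, 0, 0.1], 0.5, 0.8, False),  # below amplitude
        ],
    )
    def test_alternation_detection(self, values, amp, frac, expected):
        assert is_zigzag(values, amp, frac) is expected


class TestDeviatesFromMean:
    @pytest.mark.parametrize(
        "values, tol, expected",
        [
            ([0.5] * 6, 0.01, False),
            ([0, 0, 0, 2], 1.0, True),  # mean 0.5, max deviation 1.5
            ([0.4, 0.6], 0.2, False),  # max deviation 0.1
        ],
    )
    def test_max_deviation_thresholding(self, values, tol, expected):
        assert deviates_from_mean(values, tol) is expected
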