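"""Gaussian histogram fits, derived bounds, Welch test, SEM, correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endloop.errors import DomainError, FitError
from endloop.stats import (
    GaussianFitResult,
    WidthConvention,
    fit_gaussian,
    fit_gaussian_histogram,
    pearson_linfit,
    scale_width,
    sem,
    sigma_confidence,
    upper_bound_95,
    welch_test,
)
from endloop.synthetic_data import sample_gaussian


def _fit_result(center: float, width: float) -> GaussianFitResult:
    return GaussianFitResult(
        center=center, center_sd=0.0, width_w=width, width_sd=0.0,
        amplitude=1.0, bin_width=2.0, n_points=0,
    )


class TestFitGaussian:
    def test_noiseless_histogram_recovered_to_machine_precision(self):
        centers = np.arange(0.0, 16.0, 0.5)
        counts = 10.0 * np.exp(-((centers - 7.7) ** 2) / 2.6**2)
        fit = fit_gaussian_histogram(centers, counts, bin_width=0.5, n_points=0)
        assert fit.center == pytest.approx(7.7, abs=1e-9)
        assert fit.width_w == pytest.approx(2.6, abs=1e-9)
        assert fit.amplitude == pytest.approx(10.0, abs=1e-9)

    def test_parameter_recovery_on_synthetic_sample(self):
        values = sample_gaussian(5000, center=9.0, width_w=6.03, seed=11)
        fit = fit_gaussian(values, bin_width=2.0)
        assert abs(fit.center - 9.0) < 3 * max(fit.center_sd, 1e-6) + 0.2
        assert abs(fit.width_w - 6.03) < 0.1 * 6.03 + 3 * fit.width_sd

    def test_degenerate_sample_raises_not_silently_answers(self):
        with pytest.raises(FitError, match="equal"):
            fit_gaussian([4.2] * 50)

    def test_too_few_values_rejected(self):
        with pytest.raises(DomainError):
            fit_gaussian([1.0] * 9)

    def test_bin_width_recorded(self):
        values = sample_gaussian(500, 8.0, 4.0, seed=3)
        assert fit_gaussian(values, bin_width=1.5).bin_width == 1.5

    def test_sigma_width_round_trip(self):
        fit = _fit_result(9.0, 6.03)
        assert fit.sigma * math.sqrt(2) == pytest.approx(fit.width_w)


class TestUpperBound95:
    def test_native_fit_parameters_give_printed_bound(self):
        assert round(upper_bound_95(_fit_result(9.0, 6.03)), 1) == 17.5
        assert upper_bound_95(_fit_result(9.0, 6.03)) == pytest.approx(17.53, abs=0.005)

    def test_random_fit_parameters_give_printed_bound(self):
        assert round(upper_bound_95(_fit_result(7.7, 2.6)), 1) == 11.4
        assert upper_bound_95(_fit_result(7.7, 2.6)) == pytest.approx(11.38, abs=0.005)

    def test_unit_width_at_zero_center(self):
        assert upper_bound_95(_fit_result(0.0, 1.0)) == pytest.approx(math.sqrt(2))

    def test_alternative_sigma_convention(self):
        assert upper_bound_95(
            _fit_result(0.0, 1.0), WidthConvention.SIGMA
        ) == pytest.approx(1.645)

    @settings(max_examples=50, deadline=None)
    @given(
        c=st.floats(min_value=0, max_value=20),
        w=st.floats(min_value=0.1, max_value=10),
        dc=st.floats(min_value=0.01, max_value=5),
    )
    def test_strictly_increasing_in_center_and_width(self, c, w, dc):
        base = upper_bound_95(_fit_result(c, w))
        assert upper_bound_95(_fit_result(c + dc, w)) > base
        assert upper_bound_95(_fit_result(c, w + dc)) > base


class TestScaleWidth:
    def test_center_ratio_scaling(self):
        scaled = scale_width(2.6, center_native=9.0, center_random=7.7)
        assert scaled.value == pytest.approx(3.0390, abs=5e-4)
        assert round(scaled.value, 2) == 3.04

    def test_equal_centers_identity(self):
        assert scale_width(2.6, 5.0, 5.0).value == pytest.approx(2.6)

    def test_gc_factor_linearity(self):
        assert scale_width(2.6, 5.0, 5.0, gc_factor=2.0).value == pytest.approx(5.2)

    def test_quadrature_propagation(self):
        scaled = scale_width(
            2.0, 10.0, 5.0, w_random_sd=0.2, center_native_sd=1.0, center_random_sd=0.5
        )
        rel = math.sqrt(0.1**2 + 0.1**2 + 0.1**2)
        assert scaled.sd == pytest.approx(4.0 * rel)

    def test_zero_random_center_rejected(self):
        with pytest.raises(DomainError):
            scale_width(2.6, 9.0, 0.0)


class TestSigmaConfidence:
    def test_published_width_excess(self):
        assert round(sigma_confidence(6.03, 3.03, 0.81), 1) == 3.7

    def test_equal_widths_zero(self):
        assert sigma_confidence(3.0, 3.0, 0.5) == 0.0

    def test_plain_arithmetic(self):
        assert sigma_confidence(5.0, 3.0, 1.0) == pytest.approx(2.0)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(DomainError):
            sigma_confidence(5.0, 3.0, 0.0)


class TestWelch:
    def test_identical_samples(self):
        res = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_evaluated_formulas(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 11.0, 12.0, 13.0])
        # independent arithmetic: s^2 = 5/3 each, se = sqrt(2 * (5/3) / 4)
        se = math.sqrt(2 * (5 / 3) / 4)
        t_expected = (x.mean() - y.mean()) / se  # = -9.8590...
        dof_expected = (2 * (5 / 3) / 4) ** 2 / (2 * ((5 / 3) / 4) ** 2 / 3)  # = 6.0
        res = welch_test(x, y)
        assert res.t_statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.t_statistic == pytest.approx(-9.85900603, abs=1e-6)
        assert res.dof == pytest.approx(dof_expected, rel=1e-9)
        assert 0 < res.p_value < 1e-3

    def test_symmetry_in_sample_order(self):
        x = [1.0, 5.0, 2.0, 8.0]
        y = [2.0, 2.5, 3.0]
        assert welch_test(x, y).p_value == pytest.approx(welch_test(y, x).p_value)

    def test_dof_bounded_by_pooled(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 3, 15)
        res = welch_test(x, y)
        assert res.dof <= 10 + 15 - 2

    def test_undersized_sample_rejected(self):
        with pytest.raises(DomainError):
            welch_test([1.0], [1.0, 2.0])

    def test_conflicting_constants_rejected(self):
        with pytest.raises(DomainError):
            welch_test([2.0, 2.0], [3.0, 3.0])


class TestSem:
    def test_constant_sample(self):
        assert sem([5.0, 5.0, 5.0]) == 0.0

    def test_two_point_sample(self):
        # sd = sqrt(2), sem = sqrt(2)/sqrt(2) = 1
        assert sem([0.0, 2.0]) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(
        c=st.floats(min_value=-100, max_value=100),
        vals=st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=20),
    )
    def test_homogeneity(self, c, vals):
        scaled = [c * v for v in vals]
        assert sem(scaled) == pytest.approx(abs(c) * sem(vals), abs=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(DomainError):
            sem([1.0])


class TestPearsonLinfit:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = pearson_linfit(x, 2 * x)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_rejected(self):
        with pytest.raises(DomainError, match="undefined|variance"):
            pearson_linfit([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(DomainError):
            pearson_linfit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 3.5, 5.0, 8.0, 9.5])
        # closed-form OLS evaluated independently
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        b = sxy / sxx
        a = y.mean() - b * x.mean()
        r = sxy / math.sqrt(sxx * ((y - y.mean()) ** 2).sum())
        fit = pearson_linfit(x, y)
        assert fit.slope == pytest.approx(b, rel=1e-12)
        assert fit.intercept == pytest.approx(a, rel=1e-12)
        assert fit.pearson_r == pytest.approx(r, rel=1e-12)
        assert fit.n == 5

    def test_slope_sign_matches_r(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 40)
        y = -0.5 * x + rng.normal(0, 1, 40)
        fit = pearson_linfit(x, y)
        assert math.copysign(1, fit.slope) == math.copysign(1, fit.pearson_r)
        assert -1 <= fit.pearson_r <= 1

    def test_confidence_band_contains_fitted_line_center(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 50)
        y = 1.0 + 0.7 * x + rng.normal(0, 0.5, 50)
        fit = pearson_linfit(x, y)
        xs = np.array([x.mean()])
        lo, hi = fit.band(xs)
        mid = fit.intercept + fit.slope * xs
        assert lo[0] < mid[0] < hi[0]

    def test_uncertainty_calibration(self):
        """Reported parameter SEs cover the truth at roughly the nominal rate."""
        rng = np.random.default_rng(7)
        n_rep, hits_a, hits_b = 200, 0, 0
        for _ in range(n_rep):
            x = rng.uniform(0, 10, 30)
            y = 2.0 + 0.5 * x + rng.normal(0, 1.0, 30)
            fit = pearson_linfit(x, y)
            if abs(fit.intercept - 2.0) < 2 * fit.intercept_sd:
                hits_a += 1
            if abs(fit.slope - 0.5) < 2 * fit.slope_sd:
                hits_b += 1
        assert hits_a / n_rep >= 0.90
        assert hits_b / n_rep >= 0.90
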