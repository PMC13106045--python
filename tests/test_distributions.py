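"""Intake-distribution construction, moments, cdf and the mean shift."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from fortisim import IntakeDistribution, InvalidParameterError, shift_distribution

FAMILIES = ["lognormal", "gamma"]

families = st.sampled_from(FAMILIES)
means = st.floats(0.1, 1000.0)
cvs = st.floats(0.05, 1.5)


class TestConstruction:
    def test_gamma_from_mean_cv_gives_forced_parameters(self):
        dist = IntakeDistribution.from_mean_cv("gamma", mean=2.0, cv=0.5)
        assert dist.param1 == pytest.approx(4.0)  # shape = 1/cv^2
        assert dist.param2 == pytest.approx(0.5)  # scale = mean*cv^2
        mean, sd, cv = dist.moments()
        assert (mean, sd, cv) == pytest.approx((2.0, 1.0, 0.5))

    def test_lognormal_closed_form_moments(self):
        dist = IntakeDistribution.from_params("lognormal", 0.0, 1.0)
        assert dist.mean == pytest.approx(math.exp(0.5))

    @pytest.mark.parametrize("family", FAMILIES)
    def test_quadrature_mean_matches_analytic(self, family):
        """Numerically integrated mean of the density equals the stated mean."""
        dist = IntakeDistribution.from_mean_cv(family, mean=300.0, cv=0.4)
        upper = float(dist.quantile(1 - 1e-12))
        value, _ = integrate.quad(lambda x: x * dist.pdf(x), 0, upper, limit=200)
        assert value == pytest.approx(300.0, rel=1e-6)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_quadrature_sd_matches_analytic(self, family):
        dist = IntakeDistribution.from_mean_cv(family, mean=10.0, cv=0.6)
        upper = float(dist.quantile(1 - 1e-13))
        second, _ = integrate.quad(
            lambda x: (x - dist.mean) ** 2 * dist.pdf(x), 0, upper, limit=200
        )
        assert math.sqrt(second) == pytest.approx(dist.sd, rel=1e-6)

    @pytest.mark.parametrize(
        "family,mean,cv", [("lognormal", -1, 0.3), ("gamma", 2, 0), ("gamma", 0, 0.5)]
    )
    def test_invalid_parameters_rejected(self, family, mean, cv):
        with pytest.raises(InvalidParameterError):
            IntakeDistribution.from_mean_cv(family, mean, cv)

    @given(families, means, cvs)
    def test_native_parameter_round_trip(self, family, mean, cv):
        dist = IntakeDistribution.from_mean_cv(family, mean, cv)
        back = IntakeDistribution.from_params(family, dist.param1, dist.param2)
        assert back.mean == pytest.approx(mean, rel=1e-9)
        assert back.cv == pytest.approx(cv, rel=1e-9)

    def test_monte_carlo_mean_within_three_standard_errors(self):
        rng = np.random.default_rng(1)
        n = 10**6
        for family in FAMILIES:
            dist = IntakeDistribution.from_mean_cv(family, 5.0, 0.4)
            draws = dist.sample(n, rng)
            se = draws.std(ddof=1) / math.sqrt(n)
            assert abs(draws.mean() - dist.mean) < 3 * se


class TestCdf:
    def test_lognormal_median_is_exp_mu(self):
        dist = IntakeDistribution.from_params("lognormal", 1.3, 0.7)
        assert float(dist.cdf(math.exp(1.3))) == pytest.approx(0.5)

    def test_unit_exponential_closed_form(self):
        dist = IntakeDistribution.from_params("gamma", 1.0, 1.0)
        assert float(dist.cdf(1.0)) == pytest.approx(1 - math.exp(-1))

    @given(families, means, cvs, st.sampled_from([0.1, 0.5, 0.9]))
    def test_quantile_round_trip(self, family, mean, cv, p):
        dist = IntakeDistribution.from_mean_cv(family, mean, cv)
        assert float(dist.cdf(dist.quantile(p))) == pytest.approx(p, abs=1e-8)

    def test_point_mass_degenerate_limit(self):
        dist = IntakeDistribution.from_mean_cv("lognormal", 1.0, 1e-9)
        assert dist.quantile(0.5) == pytest.approx(1.0)
        assert float(dist.cdf(0.999)) == 0.0
        assert float(dist.cdf(1.0)) == 1.0


class TestShift:
    def test_zero_shift_is_identity(self):
        dist = IntakeDistribution.from_mean_cv("gamma", 2.0, 0.5)
        assert dist.shift(0.0) is dist

    def test_fig_style_contribution_shift(self):
        """A 433.2 mg/day contribution raises the mean by exactly 433.2."""
        dist = IntakeDistribution.from_mean_cv("lognormal", 612.0, 0.45)
        shifted = dist.shift(433.2)
        assert shifted.mean - dist.mean == pytest.approx(433.2, rel=1e-12)
        assert shifted.cv == dist.cv

    def test_gamma_shift_recomputed_parameters(self):
        shifted = IntakeDistribution.from_mean_cv("gamma", 2.0, 0.5).shift(1.0)
        assert shifted.param1 == pytest.approx(4.0)
        assert shifted.param2 == pytest.approx(0.75)

    def test_negative_delta_rejected(self):
        dist = IntakeDistribution.from_mean_cv("gamma", 2.0, 0.5)
        with pytest.raises(InvalidParameterError):
            dist.shift(-0.1)

    def test_sd_convention_preserves_sd(self):
        dist = IntakeDistribution.from_mean_cv("lognormal", 10.0, 0.5)
        shifted = dist.shift(5.0, convention="sd")
        assert shifted.sd == pytest.approx(dist.sd, rel=1e-12)
        assert shifted.mean == pytest.approx(15.0)

    @given(families, means, cvs, st.floats(0.0, 10.0))
    def test_shift_contract(self, family, mean, cv, delta_ratio):
        """Mean moves by exactly delta; family and CV are retained."""
        dist = IntakeDistribution.from_mean_cv(family, mean, cv)
        delta = delta_ratio * mean
        shifted = shift_distribution(dist, delta)
        assert shifted.family == dist.family
        assert shifted.mean - dist.mean == pytest.approx(delta, rel=1e-9, abs=1e-12)
        assert abs(shifted.cv - dist.cv) < 1e-9

    @given(families, means, cvs, st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_shift_composition(self, family, mean, cv, a, b):
        dist = IntakeDistribution.from_mean_cv(family, mean, cv)
        twice = dist.shift(a).shift(b)
        once = dist.shift(a + b)
        assert twice.mean == pytest.approx(once.mean, rel=1e-12)
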