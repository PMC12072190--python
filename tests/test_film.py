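import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize

import leedna as L
from leedna import (FilmParameters, UncertainValue, energy_to_temperature,
                    estimate_attenuation_length, initial_slope,
                    penetration_factor, survival_fraction)
from leedna.errors import DomainError, EstimationError, UsageError


class TestPenetrationFactor:
    def test_thin_film_limit_is_one(self):
        lam = 12.0
        assert penetration_factor(1e-9 * lam, lam) == pytest.approx(1.0, abs=1e-9)

    def test_equal_thickness_and_attenuation_length(self):
        assert penetration_factor(5.0, 5.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_ratio_3_83_matches_direct_evaluation(self):
        assert penetration_factor(3.83, 1.0) == pytest.approx(0.2554, abs=5e-5)

    def test_quarter_penetration_thickness_by_root_finding(self):
        # independent cross-check: which h/λ gives f = 0.25?
        x = optimize.brentq(lambda r: (1 - math.exp(-r)) / r - 0.25, 1.0, 10.0)
        assert x == pytest.approx(3.92, abs=0.01)
        assert penetration_factor(x, 1.0) == pytest.approx(0.25, rel=1e-10)

    def test_thick_film_limit_is_lambda_over_h(self):
        lam = 2.0
        h = 50 * lam
        assert penetration_factor(h, lam) == pytest.approx(lam / h, rel=1e-6)

    @pytest.mark.parametrize("h,lam", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_non_positive_arguments_rejected(self, h, lam):
        with pytest.raises(DomainError):
            penetration_factor(h, lam)

    @given(st.floats(min_value=1e-6, max_value=100),
           st.floats(min_value=1e-6, max_value=100))
    def test_bounded_and_decreasing_in_thickness_ratio(self, x1, x2):
        f1, f2 = penetration_factor(x1, 1.0), penetration_factor(x2, 1.0)
        assert 0 < f1 <= 1.0
        if x1 < x2:
            assert f1 > f2


class TestSurvivalFraction:
    def test_zero_cross_section_gives_p0(self, film):
        assert survival_fraction(5.0, 0.0, film) == film.P0

    def test_zero_time_gives_p0(self, film):
        assert survival_fraction(0.0, 5e-14, film) == film.P0

    def test_matches_brute_force_riemann_sum(self, film):
        """Adaptive quadrature agrees with a 10⁶-panel midpoint rule."""
        sigma, t = 5e-14, 1.0
        a = sigma * film.J * film.tau * (1 - math.exp(-t / film.tau))
        x = (np.arange(1_000_000) + 0.5) * film.h / 1_000_000
        brute = film.P0 * np.mean(np.exp(-a * np.exp(-x / film.lambda_att)))
        assert survival_fraction(t, sigma, film) == pytest.approx(brute, rel=1e-6)

    def test_non_increasing_in_time_and_cross_section(self, film):
        times = np.linspace(0, 50, 10)
        sigmas = np.linspace(0, 1e-13, 10)
        for sigma in sigmas:
            vals = [survival_fraction(t, sigma, film) for t in times]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        for t in times:
            vals = [survival_fraction(t, s, film) for s in sigmas]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_bounded_below_by_fully_charged_exponential(self, film):
        """Charging caps the fluence at Jτ, bounding survival from below."""
        sigma = 5e-14
        floor = film.P0 * math.exp(-sigma * film.J * film.tau)
        for t in (0.5, 5.0, 500.0):
            assert survival_fraction(t, sigma, film) >= floor - 1e-12

    def test_no_charging_sentinel_uses_plain_fluence(self):
        film = FilmParameters(h=20, lambda_att=12, tau=None, J=1e11, P0=100)
        # with tau -> inf the exponent is sigma*J*t exactly
        sigma, t = 5e-14, 2.0
        a = sigma * film.J * t
        x = (np.arange(100_000) + 0.5) * film.h / 100_000
        expected = film.P0 * np.mean(np.exp(-a * np.exp(-x / film.lambda_att)))
        assert survival_fraction(t, sigma, film) == pytest.approx(expected, rel=1e-5)


class TestInitialSlope:
    def test_zero_cross_section_gives_zero(self, film):
        assert initial_slope(0.0, film) == 0.0

    def test_thin_film_limit(self):
        film = FilmParameters(h=1e-5, lambda_att=12.0, tau=10.0, J=1e11, P0=100.0)
        assert initial_slope(1e-14, film) == pytest.approx(
            -film.P0 * 1e-14 * film.J, rel=1e-6)

    @pytest.mark.parametrize("tau", [0.1, 1.0, 100.0])
    def test_matches_numeric_derivative_for_any_charging_constant(self, tau):
        """The t→0 slope of the survival integral is charging-independent."""
        film = FilmParameters(h=20, lambda_att=12, tau=tau, J=1e11, P0=100)
        sigma = 5e-14
        dt = 1e-6 * tau
        numeric = (survival_fraction(2 * dt, sigma, film)
                   - survival_fraction(0.0, sigma, film)) / (2 * dt)
        assert initial_slope(sigma, film) == pytest.approx(numeric, rel=1e-4)


class TestEstimateAttenuationLength:
    @staticmethod
    def exact_slopes(lam, thicknesses, sd=0.0):
        return [(h, UncertainValue(-100.0 * penetration_factor(h, lam),
                                   sd * 100.0 * penetration_factor(h, lam)))
                for h in thicknesses]

    def test_noiseless_slopes_identify_lambda_exactly(self):
        est = estimate_attenuation_length(self.exact_slopes(12.0, [10, 15, 20]))
        assert est.value == pytest.approx(12.0, abs=1e-6)

    def test_median_estimate_robust_to_one_percent_noise(self):
        rng = np.random.default_rng(20250930)
        estimates = []
        for _ in range(500):
            slopes = [(h, UncertainValue(s.value * (1 + 0.01 * rng.standard_normal()),
                                         abs(s.value) * 0.01))
                      for h, s in self.exact_slopes(12.0, [10, 15, 20])]
            estimates.append(estimate_attenuation_length(slopes).value)
        assert abs(np.median(estimates) - 12.0) / 12.0 < 0.05

    def test_reported_sd_scales_with_slope_noise(self):
        noisy = [(h, UncertainValue(s.value, abs(s.value) * 0.01))
                 for h, s in self.exact_slopes(12.0, [10, 15, 20])]
        est = estimate_attenuation_length(noisy)
        assert 0 < est.sd < 12.0

    def test_fewer_than_two_thicknesses_rejected(self):
        with pytest.raises(UsageError):
            estimate_attenuation_length(self.exact_slopes(12.0, [10]))

    def test_identical_thicknesses_not_identifiable(self):
        slopes = [(10.0, UncertainValue(-25.0, 0.0)),
                  (10.0, UncertainValue(-25.0, 0.0))]
        with pytest.raises(EstimationError):
            estimate_attenuation_length(slopes)

    @pytest.mark.parametrize("scale", [0.5, 3.0])
    def test_scale_equivariance(self, scale):
        """Scaling all thicknesses and λ together scales the estimate."""
        base = estimate_attenuation_length(self.exact_slopes(12.0, [10, 15, 20]))
        scaled = estimate_attenuation_length(
            self.exact_slopes(12.0 * scale, [10 * scale, 15 * scale, 20 * scale]))
        assert scaled.value / base.value == pytest.approx(scale, rel=1e-5)


class TestEnergyTemperature:
    def test_room_temperature_anchor(self):
        assert energy_to_temperature(0.026) == pytest.approx(298.0)

    def test_one_ev(self):
        assert round(energy_to_temperature(1.0)) == 11462

    def test_two_ev(self):
        assert round(energy_to_temperature(2.0)) == 22923

    def test_non_positive_energy_rejected(self):
        with pytest.raises(DomainError):
            energy_to_temperature(0.0)


class TestFilmParameters:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(DomainError):
            FilmParameters(h=-1, lambda_att=12, tau=10, J=1e11, P0=100)
        with pytest.raises(DomainError):
            FilmParameters(h=20, lambda_att=12, tau=10, J=1e11, P0=0)

    def test_config_file_round_trip(self, tmp_path, film):
        path = tmp_path / "film.cfg"
        film.to_file(path)
        assert FilmParameters.from_file(path) == film

    def test_no_charging_round_trip(self, tmp_path):
        film = FilmParameters(h=20, lambda_att=12, tau=None, J=1e11, P0=90)
        path = tmp_path / "film.cfg"
        film.to_file(path)
        assert FilmParameters.from_file(path).charging_disabled
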