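"""Rate functions: sigmoids, regularized neocytolysis switch, boundary influx."""

import numpy as np
import pytest
import sympy as sp

import epodyn as ed
from epodyn.rates import dheaviside_reg, dneo_factor, neo_factor


class TestHeaviside:
    def test_plateaus_exact(self):
        eps = 0.7
        assert ed.heaviside_reg(0.0, eps) == 0.0
        assert ed.heaviside_reg(-3.0, eps) == 0.0
        assert ed.heaviside_reg(eps, eps) == 1.0
        assert ed.heaviside_reg(5.0, eps) == 1.0

    def test_midpoint_value(self):
        # direct polynomial evaluation at s = eps/2
        for eps in (0.5, 1.0, 2.5):
            assert ed.heaviside_reg(eps / 2, eps) == pytest.approx(0.34375, abs=1e-14)

    def test_c2_joins_by_symbolic_differentiation(self):
        s, e = sp.symbols("s eps", positive=True)
        poly = s**4 / e**6 * (10 * s**2 - 24 * e * s + 15 * e**2)
        d1 = sp.diff(poly, s)
        d2 = sp.diff(poly, s, 2)
        assert sp.simplify(poly.subs(s, 0)) == 0
        assert sp.simplify(poly.subs(s, e)) == 1
        assert sp.simplify(d1.subs(s, 0)) == 0
        assert sp.simplify(d1.subs(s, e)) == 0
        assert sp.simplify(d2.subs(s, 0)) == 0
        assert sp.simplify(d2.subs(s, e)) == 0
        # and the implemented derivative matches the symbolic one inside the band
        dd = sp.lambdify((s, e), d1)
        grid = np.linspace(0.05, 0.95, 7)
        np.testing.assert_allclose(dheaviside_reg(grid, 1.0), dd(grid, 1.0), rtol=1e-12)

    def test_range_and_monotonicity(self):
        grid = np.linspace(-1, 2, 301)
        h = ed.heaviside_reg(grid, 1.0)
        assert np.all((h >= 0.0) & (h <= 1.0))
        assert np.all(np.diff(h) >= -1e-15)

    def test_rejects_bad_eps(self):
        with pytest.raises(ValueError):
            ed.heaviside_reg(0.5, 0.0)


class TestSmoothMin:
    def test_exact_outside_band(self):
        eps, tau = 0.4, 2.0
        assert ed.smooth_min(3.1, tau, eps) == tau
        assert ed.smooth_min(tau, tau, eps) == tau
        assert ed.smooth_min(tau - eps, tau, eps) == pytest.approx(tau - eps, abs=1e-14)
        assert ed.smooth_min(0.3, tau, eps) == pytest.approx(0.3, abs=1e-14)

    def test_band_value_between_min_and_tau(self):
        eps, tau = 0.4, 2.0
        s = tau - eps / 2
        v = ed.smooth_min(s, tau, eps)
        assert s < v < tau
        # continuity across the band edges
        grid = np.linspace(tau - 2 * eps, tau + eps, 401)
        vals = ed.smooth_min(grid, tau, eps)
        assert np.max(np.abs(np.diff(vals))) < 0.02


class TestSigmoids:
    def test_alpha2_midpoint_and_limits(self, default_patient):
        p = default_patient
        mid = p.mu[2] / p.mu[1]
        assert ed.alpha2(mid, p) == pytest.approx(p.mu[0] / 2, rel=1e-12)
        assert ed.alpha2(1e7, p) == pytest.approx(0.0, abs=1e-12)
        E = np.linspace(10, 500, 200)
        a = ed.alpha2(E, p)
        assert np.all(np.diff(a) < 0) and np.all((a > 0) & (a < p.mu[0]))

    def test_nu_midpoint_and_limits(self, default_patient):
        p = default_patient
        mid = p.mu[6] / p.mu[5]
        assert ed.nu(mid, p) == pytest.approx((p.mu[3] + p.mu[4]) / 2, rel=1e-12)
        assert ed.nu(1e7, p) == pytest.approx(p.mu[3], rel=1e-9)
        E = np.linspace(10, 500, 200)
        v = ed.nu(E, p)
        assert np.all(np.diff(v) > 0) and np.all((v > p.mu[4]) & (v < p.mu[3]))

    def test_derivatives_match_finite_differences(self, default_patient):
        from epodyn.rates import dalpha2, dnu

        p = default_patient
        E = np.linspace(15, 400, 40)
        h = 1e-5
        np.testing.assert_allclose(
            dalpha2(E, p), (ed.alpha2(E + h, p) - ed.alpha2(E - h, p)) / (2 * h), rtol=1e-6
        )
        np.testing.assert_allclose(
            dnu(E, p), (ed.nu(E + h, p) - ed.nu(E - h, p)) / (2 * h), rtol=1e-6
        )


class TestAlpha5:
    def test_baseline_above_threshold_and_outside_window(self, default_patient):
        p = default_patient
        assert ed.alpha5_reg(5.0, p.tau_E + 1.0, p) == p.alpha5_0
        assert ed.alpha5_reg(5.0, 500.0, p) == p.alpha5_0
        assert ed.alpha5_reg(p.neo_window[1] + 1.0, 30.0, p) == p.alpha5_0

    def test_matches_unregularized_formula_away_from_bands(self, default_patient):
        from epodyn.rates import min_band

        p = default_patient
        E = 40.0  # below tau_E - eps, and the power term clear of the cap band
        raw = p.mu[7] / E ** p.mu[8]
        assert E <= p.tau_E - p.epsilon
        assert raw <= p.mu[9] - min_band(p) or raw >= p.mu[9]
        expect = p.alpha5_0 + min(raw, p.mu[9])
        assert ed.alpha5_reg(3.0, E, p) == pytest.approx(expect, rel=1e-12)

    def test_pointwise_convergence_as_eps_to_zero(self, default_patient):
        import dataclasses

        p = default_patient
        E_grid = np.linspace(20.0, 120.0, 101)
        x = 4.0
        raw = p.alpha5_0 + np.where(
            E_grid <= p.tau_E, np.minimum(p.mu[7] / E_grid ** p.mu[8], p.mu[9]), 0.0
        )
        rho = p.mu[7] / E_grid ** p.mu[8]
        for eps in (1.0, 0.1, 0.01):
            from epodyn.rates import min_band

            pe = dataclasses.replace(p, epsilon=eps)
            bandm = min_band(pe)
            off_band = (np.abs(E_grid - p.tau_E) > eps) & (
                (rho >= p.mu[9]) | (rho <= p.mu[9] - bandm)
            )
            assert off_band.sum() > 50  # the exceptional set shrinks with eps
            reg = np.array([ed.alpha5_reg(x, E, pe) for E in E_grid])
            np.testing.assert_allclose(reg[off_band], raw[off_band], atol=1e-12)

    def test_neo_factor_derivative_matches_fd(self, default_patient):
        p = default_patient
        E = np.linspace(20, 110, 181)  # crosses the regularization band
        h = 1e-6
        fd = (neo_factor(E + h, p) - neo_factor(E - h, p)) / (2 * h)
        np.testing.assert_allclose(dneo_factor(E, p), fd, rtol=1e-4, atol=1e-10)

    def test_smooth_and_finite_over_admissible_range(self, default_patient):
        p = default_patient
        E = np.linspace(1.0, 10 * p.tau_E, 2000)
        for fn in (ed.alpha2, ed.nu, lambda e, q: neo_factor(e, q)):
            vals = fn(E, p)
            assert np.all(np.isfinite(vals))


class TestBoundaryInflux:
    def test_class1_is_S0(self, default_patient):
        p = default_patient
        assert ed.boundary_influx(1, 123.0, 10.0, p) == p.S0
        assert ed.boundary_influx(1, 0.0, 400.0, p) == p.S0

    def test_pass_through_and_velocity_scaling(self, default_patient):
        p = default_patient
        E = 75.0
        v = ed.nu(E, p)
        assert ed.boundary_influx(2, 4.2, E, p) == 4.2
        assert ed.boundary_influx(3, 4.2, E, p) == 4.2
        assert ed.boundary_influx(4, 4.2, E, p) == pytest.approx(4.2 / v)
        assert ed.boundary_influx(5, 4.2, E, p) == pytest.approx(v * 4.2)
        assert ed.boundary_influx(4, 0.0, E, p) == 0.0

    def test_flux_conversion_round_trip(self, default_patient):
        # density entering class 4 times nu recovers the upstream flux
        p = default_patient
        E = 88.0
        g4 = ed.boundary_influx(4, 9.9, E, p)
        assert g4 * ed.nu(E, p) == pytest.approx(9.9)

    def test_invalid_class(self, default_patient):
        with pytest.raises(ValueError):
            ed.boundary_influx(6, 1.0, 50.0, default_patient)
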