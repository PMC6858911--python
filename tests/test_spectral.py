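"""Spectral basis, delta representer, operator assembly and steady states."""

import numpy as np
import pytest
from numpy.polynomial import legendre as npleg

import epodyn as ed
from epodyn.spectral import SpectralBasis, indicator_mass_matrix, operators_for

WIDTHS = [3.0, 5.0, 2.5, 80.0]


@pytest.mark.parametrize("j", [0, 1, 2, 3, 7, 14])
def test_legendre_eval_matches_reference(j, rng):
    x = rng.uniform(-1, 1, 50)
    ref = npleg.legval(x, np.eye(j + 1)[j])
    np.testing.assert_allclose(ed.legendre_eval(j, x), ref, atol=1e-12)
    # endpoint and parity identities
    assert ed.legendre_eval(j, 1.0) == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(
        ed.legendre_eval(j, -x), (-1.0) ** j * ed.legendre_eval(j, x), atol=1e-12
    )


def test_legendre_low_degree_values():
    assert ed.legendre_eval(2, 0.0) == pytest.approx(-0.5)
    assert ed.legendre_eval(3, 0.5) == pytest.approx(0.5 * (5 * 0.125 - 3 * 0.5))


@pytest.mark.parametrize("w", WIDTHS)
def test_basis_identities(w):
    N = 15
    b = SpectralBasis(N, w)
    j = np.arange(N)
    np.testing.assert_allclose(b.norms_sq, 1.0 / (2 * j + 1), rtol=1e-15)
    np.testing.assert_allclose(b.at_one, w ** -0.5 * np.ones(N), rtol=1e-15)
    np.testing.assert_allclose(b.at_zero, (-1.0) ** j * w ** -0.5, rtol=1e-15)
    # orthogonality and norms under exact quadrature
    x, wq = npleg.leggauss(2 * N)
    xi = 0.5 * (x + 1)
    V = npleg.legvander(-1 + 2 * xi, N - 1) / np.sqrt(w)
    G = w * (V * (0.5 * wq)[:, None]).T @ V
    np.testing.assert_allclose(G, np.diag(b.norms_sq), atol=1e-12)


def test_derivative_matrix_structure_and_accuracy():
    N = 15
    C = ed.derivative_matrix(N)
    assert np.all(C[0] == 0)  # L0' = 0
    np.testing.assert_allclose(C[1], np.eye(N)[0])  # L1' = L0
    # strictly lower triangular in degree
    assert np.all(np.triu(C) == 0)
    # reconstructed derivatives against the numpy legder oracle
    x = np.linspace(-1, 1, 201)
    for j in range(N):
        der = npleg.legval(x, npleg.legder(np.eye(N)[j]))
        rec = npleg.legval(x, C[j][: max(j, 1)]) if j else np.zeros_like(x)
        np.testing.assert_allclose(rec, der, atol=1e-8)


@pytest.mark.parametrize("w", [3.0, 80.0])
def test_delta_representer_reproduces_point_evaluation(w, rng):
    N = 15
    b = SpectralBasis(N, w)
    dvec = ed.delta_representer(b)
    for _ in range(10):
        c = rng.standard_normal(N)
        phi0 = float(b.evaluate(c, np.array([0.0]))[0])
        inner = float(np.sum(dvec * c * b.norms_sq))  # <delta, phi>_w
        assert inner == pytest.approx(phi0, abs=1e-12 * max(1.0, abs(phi0)))


def test_delta_representer_single_mode():
    b = SpectralBasis(1, 4.0)
    np.testing.assert_allclose(ed.delta_representer(b), [1.0 / np.sqrt(4.0)])


class TestProjection:
    def test_idempotent_on_span(self, rng):
        b = SpectralBasis(12, 5.0)
        c = rng.standard_normal(12)
        out = ed.project(lambda xi: b.evaluate(c, xi), b)
        np.testing.assert_allclose(out, c, atol=1e-11)

    def test_constant(self):
        b = SpectralBasis(10, 7.0)
        out = ed.project(lambda xi: 3.0 * np.ones_like(xi), b)
        expect = np.zeros(10)
        expect[0] = 3.0 * np.sqrt(7.0)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_indicator_against_analytic_integrals(self):
        # <chi_[0,a], e_j>_w = sqrt(w)/2 * int_{-1}^{2a-1} L_j; use legint oracle
        b = SpectralBasis(15, 5.0)
        a = 0.37
        out = ed.project(lambda xi: (xi <= a).astype(float), b, breaks=(a,))
        for j in range(15):
            anti = npleg.legint(np.eye(15)[j])
            integral = npleg.legval(2 * a - 1, anti) - npleg.legval(-1, anti)
            expect = np.sqrt(5.0) / 2.0 * integral * (2 * j + 1)
            assert out[j] == pytest.approx(expect, abs=1e-12)


class TestAssembly:
    def test_class1_independent_of_E(self, default_patient):
        A_lo, d = ed.assemble_operator(1, 25.0, default_patient)
        A_hi, _ = ed.assemble_operator(1, 400.0, default_patient)
        np.testing.assert_array_equal(A_lo, A_hi)
        b = SpectralBasis(15, 3.0)
        np.testing.assert_allclose(d, b.at_zero / b.norms_sq)

    def test_class5_above_threshold_is_baseline_mortality(self, default_patient):
        p = default_patient
        A, _ = ed.assemble_operator(5, p.tau_E + 5.0, p)
        ops = operators_for(p, 15)
        baseline = ops.A0[4]
        np.testing.assert_allclose(A, baseline, atol=1e-14)

    @pytest.mark.parametrize("i,E", [(1, 50.0), (2, 70.0), (4, 120.0), (5, 45.0)])
    def test_action_matches_direct_operator_evaluation(self, i, E, default_patient, rng):
        # A c versus projection-based evaluation of -(v/w) phi' + P(kappa phi) - delta phi(0)
        from epodyn import rates as rt

        p = default_patient
        N = 15
        w = p.geometry.widths[i - 1]
        b = SpectralBasis(N, w)
        A, _ = ed.assemble_operator(i, E, p, N)
        c = rng.standard_normal(N)
        v = rt.nu(E, p) if i == 4 else 1.0
        kconst = {1: p.beta1, 2: p.beta2 - rt.alpha2(E, p), 4: -p.alpha4}.get(i)

        dcoef = npleg.legder(c)  # derivative in the Legendre variable

        def phi(xi):
            return b.evaluate(c, xi)

        def dphi(xi):
            return 2.0 / np.sqrt(w) * npleg.legval(-1 + 2 * xi, dcoef)

        if i == 5:
            lo, hi = p.neo_window
            kap = lambda xi: -rt.alpha5_reg(w * xi, E, p)
            breaks = (lo / w, hi / w)
        else:
            kap = lambda xi: kconst * np.ones_like(xi)
            breaks = ()
        expected = (
            ed.project(lambda xi: -(v / w) * dphi(xi) + kap(xi) * phi(xi), b, breaks=breaks)
            - b.delta * phi(np.array([0.0]))[0]
        )
        np.testing.assert_allclose(A @ c, expected, rtol=1e-10, atol=1e-10 * np.abs(expected).max())


class TestSteadyState:
    def test_class1_analytic_solution_and_spectral_decay(self, default_patient):
        p = default_patient
        errs = []
        for N in (4, 8, 12, 15):
            y = ed.steady_state_class(1, p.E_end, p.S0, p, N)
            b = SpectralBasis(N, 3.0)
            x, wq = npleg.leggauss(80)
            xi = 0.5 * (x + 1)
            yh = b.evaluate(y, xi)
            ytrue = p.S0 * np.exp(p.beta1 * 3.0 * xi)
            num = np.sqrt(np.sum(0.5 * wq * (yh - ytrue) ** 2))
            den = np.sqrt(np.sum(0.5 * wq * ytrue**2))
            errs.append(num / den)
        assert errs[-1] < 1e-6
        # faster than any fixed polynomial rate: successive ratios shrink
        assert errs[1] / errs[0] < 0.1
        assert errs[2] / errs[1] < 0.1

    def test_linearity_in_influx(self, default_patient):
        p = default_patient
        y1 = ed.steady_state_class(2, 70.0, 4.0, p)
        y2 = ed.steady_state_class(2, 70.0, 8.0, p)
        np.testing.assert_allclose(y2, 2.0 * y1, rtol=1e-12)

    def test_class4_throughput_conserved_when_lossless(self, default_patient):
        import dataclasses

        from epodyn import rates as rt

        p = dataclasses.replace(default_patient, alpha4=0.0)
        E = 90.0
        influx_flux = 7.0  # cells/day entering class 4
        g4 = influx_flux / rt.nu(E, p)
        y4 = ed.steady_state_class(4, E, g4, p)
        out_flux = rt.nu(E, p) * SpectralBasis(15, 2.5).boundary_value(y4)
        assert out_flux == pytest.approx(influx_flux, rel=1e-8)

    def test_full_chain_population_identity(self, default_patient, default_steady):
        # total population observable equals quadrature of the reconstructed density
        p = default_patient
        w5 = p.geometry.widths[4]
        b5 = SpectralBasis(15, w5)
        x, wq = npleg.leggauss(100)
        xi = 0.5 * (x + 1)
        dens = b5.evaluate(default_steady.coeffs[4], xi)
        P_quad = w5 * np.sum(0.5 * wq * dens) * 1e8
        assert default_steady.population(p) == pytest.approx(P_quad, rel=1e-10)

    def test_doubling_S0_doubles_all_densities(self, default_patient):
        import dataclasses

        p = default_patient
        p2 = dataclasses.replace(p, S0=2 * p.S0)
        s1 = ed.steady_state(p)
        s2 = ed.steady_state(p2)
        np.testing.assert_allclose(s2.coeffs, 2 * s1.coeffs, rtol=1e-10)


def test_indicator_mass_matrix_full_window_is_identityish():
    b = SpectralBasis(10, 5.0)
    K = indicator_mass_matrix(b, 0.0, 1.0)
    np.testing.assert_allclose(K, np.eye(10), atol=1e-12)
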