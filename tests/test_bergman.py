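"""Glucose-insulin kinetics: field, equilibrium, linearization, transfer view."""

import numpy as np
import pytest
import sympy as sp

from mcpsim.bergman import (
    BergmanParams,
    DisturbanceInput,
    GlucoseInsulinState,
    OperatingPoint,
    bmm_derivatives,
    equilibrium_point,
    linearize,
    linearized_derivatives,
    ss_to_transfer_gains,
)

P = BergmanParams()


def _random_params(rng):
    return BergmanParams(
        p1=rng.uniform(0.01, 0.05),
        p2=rng.uniform(0.01, 0.05),
        p3=rng.uniform(1e-6, 1e-4),
        n=rng.uniform(0.05, 0.3),
        Gb=rng.uniform(60, 100),
        Ib=rng.uniform(5, 20),
        tau=rng.uniform(0.5, 2.0),
    )


class TestDerivatives:
    def test_basal_rest_point(self):
        state = GlucoseInsulinState(G=P.Gb, X=0.0, I=P.Ib)
        assert np.allclose(bmm_derivatives(state, P, DisturbanceInput()), 0.0)

    def test_decoupled_meal_response(self):
        state = GlucoseInsulinState(G=100.0, X=0.0, I=P.Ib)
        u = DisturbanceInput(D=2.0)
        dG, dX, dI = bmm_derivatives(state, P, u)
        assert dG == pytest.approx(-P.p1 * (100.0 - P.Gb) + 2.0)
        assert dX == 0.0 and dI == 0.0

    def test_matches_symbolic_field_term_by_term(self):
        """Independent sympy evaluation of the three compartment ODEs."""
        G, X, I, D, C, r, t = sp.symbols("G X I D C r t", positive=True)
        p1, p2, p3, n, gam, h, Gb, Ib, tau = sp.symbols("p1 p2 p3 n gam h Gb Ib tau")
        field = [
            -p1 * (G - Gb) - X * G + (D + C),
            -p2 * X + p3 * (I - Ib),
            -n * (I - Ib) + gam * sp.Max(G - h, 0) * t + tau * r,
        ]
        subs = {
            G: 140.0, X: 0.002, I: 22.0, D: 1.5, C: 0.3, r: 0.8, t: 12.0,
            p1: P.p1, p2: P.p2, p3: P.p3, n: P.n, gam: P.gamma, h: P.h,
            Gb: P.Gb, Ib: P.Ib, tau: P.tau,
        }
        expected = [float(f.subs(subs)) for f in field]
        got = bmm_derivatives(
            GlucoseInsulinState(G=140.0, X=0.002, I=22.0),
            P,
            DisturbanceInput(D=1.5, C=0.3, r=0.8),
            t=12.0,
            include_gamma=True,
        )
        assert np.allclose(got, expected, rtol=1e-12)

    def test_gamma_off_drops_endogenous_term(self):
        state = GlucoseInsulinState(G=P.h + 50.0, X=0.0, I=P.Ib)
        with_g = bmm_derivatives(state, P, DisturbanceInput(), t=10.0, include_gamma=True)
        without = bmm_derivatives(state, P, DisturbanceInput(), t=10.0, include_gamma=False)
        assert with_g[2] - without[2] == pytest.approx(P.gamma * 50.0 * 10.0)


class TestLinearizedField:
    def test_equals_nonlinear_when_xbar_zero(self):
        op = equilibrium_point(P)  # X0 = 0 at zero inputs
        state = GlucoseInsulinState(G=123.0, X=0.0, I=P.Ib)
        u = DisturbanceInput(D=1.0)
        assert np.allclose(
            linearized_derivatives(state, P, u, op), bmm_derivatives(state, P, u)
        )

    def test_equilibrium_of_its_own_linearization(self):
        op = equilibrium_point(P, (0.5, 0.2, 0.6))
        assert np.allclose(linearized_derivatives(op.x0, P, op.u0, op), 0.0, atol=1e-12)

    def test_quadratic_error_scaling(self):
        """Richardson: the nonlinear/linearized gap shrinks 4x when the
        perturbation is halved (the gap is exactly bilinear)."""
        op = equilibrium_point(P, (1.0, 0.0, 0.5))
        rng = np.random.default_rng(3)
        delta = rng.normal(size=3) * np.array([5.0, 1e-3, 2.0])
        u = op.u0

        def gap(d):
            x = op.x0 + d
            return np.linalg.norm(
                bmm_derivatives(x, P, u) - linearized_derivatives(x, P, u, op)
            )

        assert gap(delta) / gap(delta / 2) == pytest.approx(4.0, rel=1e-6)


class TestEquilibrium:
    def test_zero_inputs_give_basal(self):
        op = equilibrium_point(P, (0.0, 0.0, 0.0))
        assert (op.G0, op.X0, op.I0) == pytest.approx((P.Gb, 0.0, P.Ib))

    def test_disturbance_without_insulin(self):
        op = equilibrium_point(P, (1.0, 0.5, 0.0))
        assert op.G0 == pytest.approx(P.Gb + 1.5 / P.p1)
        assert op.X0 == 0.0
        assert op.I0 == pytest.approx(P.Ib)

    def test_residual_vanishes_over_random_parameter_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            params = _random_params(rng)
            u0 = (rng.uniform(0, 3), rng.uniform(0, 1), rng.uniform(0, 2))
            op = equilibrium_point(params, u0)
            res = bmm_derivatives(op.x0, params, op.u0, include_gamma=False)
            assert np.max(np.abs(res)) < 1e-9


class TestLinearize:
    def test_matrix_entries_at_basal(self):
        op = equilibrium_point(P)
        m = linearize(P, op)
        assert m.A[0, 0] == pytest.approx(-P.p1)
        assert m.A[0, 1] == pytest.approx(-P.Gb)
        assert np.allclose(m.B[:, 2], [0.0, 0.0, P.tau])

    def test_triangular_spectrum_stable(self):
        rng = np.random.default_rng(11)
        params = _random_params(rng)
        op = equilibrium_point(params, (0.4, 0.1, 1.0))
        m = linearize(params, op)
        eig = np.linalg.eigvals(m.A)
        assert np.allclose(sorted(eig), sorted([-params.p1 - op.X0, -params.p2, -params.n]))
        assert np.all(eig.real < 0)

    def test_matches_numerical_jacobian(self):
        op = equilibrium_point(P, (0.8, 0.0, 0.7))
        m = linearize(P, op)
        h = 1e-5
        J = np.zeros((3, 3))
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            J[:, j] = (
                bmm_derivatives(op.x0 + e, P, op.u0) - bmm_derivatives(op.x0 - e, P, op.u0)
            ) / (2 * h)
        assert np.max(np.abs(J - m.A)) < 1e-6


class TestTransferGains:
    def test_meal_channel_pole_cancellation_at_basal(self):
        """With X0 = 0 the D->G transfer collapses to 1/(s + p1)."""
        m = linearize(P, equilibrium_point(P))
        num, den = ss_to_transfer_gains(m, "D")
        for s in (0.0, 0.01j, 0.1 + 0.05j, 1.0):
            T = np.polyval(num, s) / np.polyval(den, s)
            assert T == pytest.approx(1.0 / (s + P.p1), rel=1e-9)

    def test_dc_gain_matches_step_response(self):
        """Static gain of the meal channel equals the steady-state glucose
        shift per unit sustained disturbance in a long linear simulation."""
        op = equilibrium_point(P)
        m = linearize(P, op)
        num, den = ss_to_transfer_gains(m, "D")
        dc = np.polyval(num, 0.0) / np.polyval(den, 0.0)
        x = op.x0.copy()
        u = np.array([0.5, 0.0, 0.0])
        dt = 0.05
        for k in range(int(3000 / dt)):
            x = x + dt * linearized_derivatives(x, P, u, op)
        assert dc == pytest.approx((x[0] - op.G0) / 0.5, rel=1e-3)

    def test_insulin_channel_numerator_scales_with_tau(self):
        p2 = BergmanParams(tau=2 * P.tau)
        m1 = linearize(P, equilibrium_point(P))
        m2 = linearize(p2, equilibrium_point(p2))
        n1, _ = ss_to_transfer_gains(m1, "r")
        n2, _ = ss_to_transfer_gains(m2, "r")
        lead1 = n1[np.nonzero(np.abs(n1) > 1e-12)[0][0]]
        lead2 = n2[np.nonzero(np.abs(n2) > 1e-12)[0][0]]
        assert lead2 / lead1 == pytest.approx(2.0)

    def test_denominator_is_characteristic_polynomial(self):
        op = equilibrium_point(P, (0.3, 0.0, 0.4))
        m = linearize(P, op)
        _, den = ss_to_transfer_gains(m, "r")
        expected = np.poly([-P.p1 - op.X0, -P.p2, -P.n])
        assert np.allclose(den / den[0], expected)
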