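"""Method-of-lines solver: sources, conservation, fronts, rates."""

import numpy as np
import pytest

from matrixrelease.analytic import critical_time, surface_undissolved
from matrixrelease.core import DimensionlessParams, SPHERICAL
from matrixrelease.pde import (
    Mesh,
    ReleaseCurve,
    SolverOptions,
    StateProfile,
    default_output_grid,
    depletion_front,
    dissolution_source,
    release_fraction,
    release_rate,
    solve,
)


class TestDissolutionSource:
    def test_exhausted_solid_cannot_dissolve(self):
        p = DimensionlessParams(K=0.5, G=1.0, n=0.0)
        assert dissolution_source(0.1, 0.0, p) == 0.0

    def test_saturated_solution_stops_dissolution(self):
        p = DimensionlessParams(K=0.5, G=3.0, n=SPHERICAL)
        assert dissolution_source(0.5, 0.4, p) == pytest.approx(0.0, abs=1e-15)

    def test_hand_value_planar(self):
        # G * 1 * (K - 0) = 0.5
        p = DimensionlessParams(K=0.5, G=1.0, n=0.0)
        assert dissolution_source(0.0, 0.5, p) == pytest.approx(0.5, rel=1e-14)

    def test_negative_solid_clamped(self):
        p = DimensionlessParams(K=0.5, G=1.0, n=SPHERICAL)
        assert dissolution_source(0.0, -1e-12, p) == 0.0

    def test_vectorized(self):
        p = DimensionlessParams(K=0.5, G=2.0, n=0.5)
        phi = np.array([0.0, 0.25, 0.5])
        phi_a = np.array([0.5, 0.25, 0.0])
        S = dissolution_source(phi, phi_a, p)
        assert S.shape == (3,)
        assert S[2] == 0.0 and S[0] > S[1] > 0.0


class TestMeshAndOptions:
    def test_mesh_grid_endpoints(self):
        m = Mesh(101)
        assert m.eta[0] == 0.0 and m.eta[-1] == 1.0
        assert np.all(np.diff(m.eta) > 0)
        assert m.h == pytest.approx(0.01)

    def test_mesh_too_small_rejected(self):
        with pytest.raises(ValueError):
            Mesh(2)

    def test_output_grid_validation(self):
        with pytest.raises(ValueError):
            SolverOptions(output_tau=np.array([0.2, 0.1]))
        with pytest.raises(ValueError):
            SolverOptions(rel_tol=0.0)

    def test_default_output_grid_spans_critical_time(self):
        p = DimensionlessParams(K=0.5, G=1.0, n=0.0)
        grid = default_output_grid(p)
        tc = critical_time(p)
        assert grid[0] < tc < grid[-1]
        assert len(grid) == 400


class TestReleaseFraction:
    def make_state(self, eta, phi, phi_a):
        return StateProfile(tau=0.0, eta=eta, phi=phi, phi_a=phi_a)

    def test_initial_state_zero(self):
        eta = np.linspace(0, 1, 201)
        s = self.make_state(eta, np.full_like(eta, 0.3), np.full_like(eta, 0.7))
        assert release_fraction(s) == pytest.approx(0.0, abs=1e-12)

    def test_fully_depleted_is_one(self):
        eta = np.linspace(0, 1, 201)
        s = self.make_state(eta, np.zeros_like(eta), np.zeros_like(eta))
        assert release_fraction(s) == pytest.approx(1.0, rel=1e-12)

    def test_piecewise_constant_inner_half(self):
        # full concentration inside eta <= 1/2, empty outside: F = 1 - (1/2)^3
        eta = np.linspace(0, 1, 4001)
        phi = np.where(eta <= 0.5, 0.3, 0.0)
        phi_a = np.where(eta <= 0.5, 0.7, 0.0)
        s = self.make_state(eta, phi, phi_a)
        # Simpson on a discontinuous integrand is O(h) in the jump cell
        assert release_fraction(s) == pytest.approx(0.875, abs=2e-4)


class TestDepletionFront:
    def test_initial_front_at_surface(self):
        eta = np.linspace(0, 1, 101)
        s = StateProfile(0.0, eta, np.zeros_like(eta), np.full_like(eta, 0.5))
        assert depletion_front(s) == 1.0

    def test_exhausted_everywhere(self):
        eta = np.linspace(0, 1, 101)
        s = StateProfile(0.0, eta, np.zeros_like(eta), np.zeros_like(eta))
        assert depletion_front(s) == 0.0

    def test_partial_depletion(self):
        eta = np.linspace(0, 1, 101)
        phi_a = np.where(eta <= 0.63, 0.5, 0.0)
        s = StateProfile(0.0, eta, np.zeros_like(eta), phi_a)
        assert depletion_front(s) == pytest.approx(0.63, abs=0.011)


class TestReleaseRate:
    def make_curve(self, tau, F):
        p = DimensionlessParams(K=0.5, G=1.0)
        return ReleaseCurve(tau, F, np.zeros_like(tau), np.ones_like(tau), p)

    def test_exact_for_linear_fraction(self):
        tau = np.linspace(0.0, 1.0, 11)
        rate = release_rate(self.make_curve(tau, 0.37 * tau))
        np.testing.assert_allclose(rate, 0.37, rtol=1e-12)

    def test_linear_on_log_grid(self):
        tau = np.geomspace(0.01, 1.0, 30)
        rate = release_rate(self.make_curve(tau, 2.0 * tau))
        np.testing.assert_allclose(rate[1:-1], 2.0, rtol=1e-6)

    def test_duplicate_times_rejected(self):
        tau = np.array([0.1, 0.1, 0.2])
        with pytest.raises(ValueError):
            release_rate(self.make_curve(tau, tau.copy()))

    def test_short_curve_rejected(self):
        tau = np.array([0.1, 0.2])
        with pytest.raises(ValueError):
            release_rate(self.make_curve(tau, tau.copy()))


class TestSolve:
    def test_initial_condition_returned_at_tau_zero(self):
        p = DimensionlessParams(K=0.5, G=1.0, n=0.0)
        grid = np.concatenate([[0.0], np.geomspace(1e-3, 0.5, 20)])
        curve, states = solve(p, Mesh(200), SolverOptions(output_tau=grid))
        s0 = states[0]
        # the surface node is pinned to the sink from tau=0+, which leaves a
        # released-fraction offset of order K*h on an h-spaced mesh
        assert curve.fraction_released[0] == pytest.approx(0.0, abs=6e-3)
        assert curve.eta_star[0] == 1.0
        np.testing.assert_allclose(s0.phi[:-1], p.K, atol=1e-9)
        np.testing.assert_allclose(s0.phi_a, 1 - p.K, atol=1e-9)
        assert s0.phi[-1] == 0.0

    def test_surface_solid_matches_exact_solution(self, solve_cached):
        # at the surface phi = 0 exactly, so phi_a(tau, 1) has a closed form
        p = DimensionlessParams(K=0.5, G=1.0, n=0.0)
        grid = np.geomspace(1e-3, 1.0, 60)
        curve, states = solve_cached(p, 600, 1e-6, grid)
        errs = [
            abs(s.phi_a[-1] - surface_undissolved(s.tau, p)) for s in states
        ]
        assert max(errs) < 1e-3

    @pytest.mark.parametrize("n", [0.5, SPHERICAL])
    def test_surface_solid_matches_exact_solution_shaped(self, n, solve_cached):
        p = DimensionlessParams(K=0.3, G=2.0, n=n)
        tc = critical_time(p)
        grid = np.geomspace(1e-3 * tc, 0.95 * tc, 40)
        curve, states = solve_cached(p, 600, 1e-6, grid)
        errs = [
            abs(s.phi_a[-1] - surface_undissolved(s.tau, p)) for s in states
        ]
        assert max(errs) < 1e-3

    def test_mass_conservation_and_monotonicity(self, solve_cached):
        from scipy.integrate import simpson

        p = DimensionlessParams(K=0.5, G=10.0, n=SPHERICAL)
        tc = critical_time(p)
        grid = np.geomspace(1e-3 * tc, 20 * tc, 80)
        curve, states = solve_cached(p, 600, 1e-6, grid)
        for s, F in zip(states, curve.fraction_released):
            remaining = simpson((s.phi + s.phi_a) * 3 * s.eta**2, x=s.eta)
            assert F + remaining == pytest.approx(1.0, abs=2e-3)
        assert np.all(np.diff(curve.fraction_released) >= -1e-9)
        assert np.all(np.diff(curve.eta_star) <= 1e-12)
        assert np.all(curve.fraction_released <= 1.0 + 1e-3)
        # pointwise solid concentration never grows (up to integrator noise)
        stack = np.stack([s.phi_a for s in states])
        assert np.all(np.diff(stack, axis=0) <= 1e-7)

    def test_front_onset_brackets_critical_time(self, solve_cached):
        p = DimensionlessParams(K=0.5, G=1.0, n=0.0)
        tc = critical_time(p)
        grid = np.geomspace(0.01 * tc, 1.5 * tc, 120)
        curve, _ = solve_cached(p, 600, 1e-6, grid)
        departed = curve.eta_star < 1.0
        assert np.any(departed)
        first = np.argmax(departed)
        assert first > 0
        assert curve.tau[first - 1] <= tc <= curve.tau[first] * 1.05

    def test_shape_factor_ordering(self, solve_cached):
        # larger n -> smaller dissolving area -> slower release
        grid = np.geomspace(1e-3, 10.0, 50)
        fractions = {}
        for n in (0.0, 0.5, SPHERICAL):
            p = DimensionlessParams(K=0.5, G=1.0, n=n)
            curve, _ = solve_cached(p, 600, 1e-6, grid)
            fractions[n] = curve.fraction_released
        tol = 1e-6
        assert np.all(fractions[0.0] >= fractions[0.5] - tol)
        assert np.all(fractions[0.5] >= fractions[SPHERICAL] - tol)

    def test_mesh_convergence(self):
        # refinement from 1000 to 2000 nodes moves F(tau_c) by < 1e-3
        p = DimensionlessParams(K=0.5, G=10.0, n=SPHERICAL)
        tc = critical_time(p)
        grid = np.geomspace(1e-3 * tc, tc, 30)
        vals = []
        for nodes in (1000, 2000):
            curve, _ = solve(
                p, Mesh(nodes), SolverOptions(rel_tol=1e-6, output_tau=grid)
            )
            vals.append(curve.fraction_released[-1])
        assert abs(vals[1] - vals[0]) < 1e-3

    def test_rate_field_consistent_with_finite_differences(self, solve_cached):
        p = DimensionlessParams(K=0.5, G=1.0, n=0.0)
        grid = np.geomspace(1e-3, 10.0, 50)
        curve, _ = solve_cached(p, 600, 1e-6, grid)
        fd = release_rate(curve)
        mask = (curve.tau > 0.05) & (curve.tau < 0.9)
        np.testing.assert_allclose(curve.rate[mask], fd[mask], rtol=0.05)
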