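"""Reaction-diffusion solver: analytic oracle, conservation, limits."""

import dataclasses

import numpy as np
import pytest

from nucsense import (
    ConcentrationState,
    ExchangeGeometry,
    Grid1D,
    NuclearTrajectory,
    derive_dimensionless,
    footprint_average_map,
    footprint_weights,
    max_stable_dt,
    resample_trajectory,
    simulate_trajectory,
    steady_profile_closed_form,
    steady_profile_no_nucleus,
    steady_state_with_nucleus,
    transient_solve,
)


def stationary_trajectory(xi0, t_end, dt):
    n = int(round(t_end / dt))
    return NuclearTrajectory(
        times=np.arange(n + 1) * dt,
        xi=np.full(n + 1, xi0),
        phase=np.zeros(n + 1, dtype=np.int8),
        turning_position=xi0,
        pause_duration=0.0,
        seed=0,
        dt=dt,
    )


def scaled_exchange(transport, factor):
    return dataclasses.replace(
        transport,
        import_rate=transport.import_rate * factor,
        export_rate=transport.export_rate * factor,
    )


class TestSteadyNoNucleus:
    @pytest.mark.parametrize("phi", [0.5, 1.0, 10.0])
    def test_matches_closed_form(self, phi, grid):
        """Discrete solution vs θ(ξ) = φ cosh(φ(1−ξ))/sinh(φ), evaluated
        here independently with plain cosh/sinh."""
        num = steady_profile_no_nucleus(phi, grid)
        ana = phi * np.cosh(phi * (1.0 - grid.xi_centers)) / np.sinh(phi)
        assert np.max(np.abs(num / ana - 1.0)) < 1e-3

    def test_apex_base_ratio_is_cosh_phi(self, grid):
        theta = steady_profile_closed_form(10.0, np.array([0.0, 1.0]))
        assert theta[0] / theta[1] == pytest.approx(np.cosh(10.0), rel=1e-12)
        num = steady_profile_no_nucleus(10.0, Grid1D.make(2000))
        ratio = num[0] / num[-1]
        # cell centers sit dx/2 inside the boundaries; compare to the closed
        # form at the same points
        ana = steady_profile_closed_form(10.0, Grid1D.make(2000).xi_centers)
        assert ratio == pytest.approx(ana[0] / ana[-1], rel=1e-4)

    def test_small_phi_limit_uniform(self, grid):
        theta = steady_profile_closed_form(1e-4, grid.xi_centers)
        assert np.allclose(theta, 1.0, atol=1e-6)

    def test_apical_flux_condition(self, grid):
        """-dθ/dξ at the apex equals φ² (imposed production flux)."""
        for phi in (1.0, 10.0):
            theta = steady_profile_no_nucleus(phi, Grid1D.make(1000))
            dx = 1.0 / 1000
            # flux at the first interior face, one-sided second-order estimate
            flux_face = -(theta[1] - theta[0]) / dx
            interior_loss = phi * phi * theta[0] * dx
            assert flux_face + interior_loss == pytest.approx(phi * phi, rel=2e-3)

    def test_large_phi_closed_form_stable(self):
        theta = steady_profile_closed_form(5000.0, np.array([0.0, 0.5, 1.0]))
        assert np.all(np.isfinite(theta))

    def test_huge_phi_discrete_solve_errors_with_guidance(self, grid):
        with pytest.raises(ValueError, match="closed_form"):
            steady_profile_no_nucleus(1e4, grid)

    def test_steady_mass_balance(self, grid):
        """Apical influx φ² balances integrated degradation ∫φ²θ dξ."""
        for phi in (1.0, 10.0):
            theta = steady_profile_no_nucleus(phi, grid)
            degradation = phi * phi * theta.sum() * grid.dx
            assert degradation == pytest.approx(phi * phi, rel=1e-2)


class TestFootprint:
    def test_weights_sum_to_footprint_width(self, grid, exch):
        for xi in (0.12, 0.5, 0.9):
            w = footprint_weights(grid, xi, exch.nuclear_extent)
            assert w.sum() * grid.dx == pytest.approx(2 * exch.nuclear_extent, rel=1e-12)
            assert np.all((w >= 0) & (w <= 1))

    def test_conservation_identity(self, exch):
        assert exch.sink_strength * 2 * exch.nuclear_extent == pytest.approx(
            exch.beta * exch.volume_ratio, rel=1e-12
        )


class TestSteadyWithNucleus:
    def test_nuclear_gradient_contrast(self, geometry, transport, motion, exch, grid):
        """Steep gradient (φ=10): nuclear level collapses toward the base;
        shallow gradient (φ=1): it stays a substantial fraction."""
        ratios = {}
        for phi in (1.0, 10.0):
            g = derive_dimensionless(geometry, transport.with_phi(phi, geometry.length), motion)
            apex = steady_state_with_nucleus(g, exch, geometry.xi_min, grid)
            base = steady_state_with_nucleus(g, exch, geometry.xi_max, grid)
            ratios[phi] = base.theta_n / apex.theta_n
        assert ratios[10.0] < 0.05
        assert ratios[1.0] > 0.3

    def test_equal_alphas_give_footprint_average(self, geometry, motion, grid):
        from nucsense import TransportParameters

        tr = TransportParameters(diffusivity=2.9, degradation=0.0116,
                                 import_rate=5.0, export_rate=5.0)
        g = derive_dimensionless(geometry, tr, motion)
        exch = ExchangeGeometry.from_geometry(geometry)
        state = steady_state_with_nucleus(g, exch, 0.5, grid)
        w = footprint_weights(grid, 0.5, exch.nuclear_extent)
        assert state.theta_n == pytest.approx((w / w.sum()) @ state.theta_c, rel=1e-10)

    def test_inadmissible_position_rejected(self, groups, exch, grid):
        with pytest.raises(ValueError, match="admissible"):
            steady_state_with_nucleus(groups, exch, 0.05, grid)


class TestTransient:
    def test_stationary_converges_to_steady_state(self, groups, exch, grid):
        """With a parked nucleus the transient relaxes to the steady coupled
        solution (fixed point of the scheme)."""
        xi0 = 0.5
        traj = stationary_trajectory(xi0, t_end=30.0, dt=5e-3)
        ic = ConcentrationState(
            t=0.0, theta_c=steady_profile_no_nucleus(groups.phi, grid), theta_n=1.0, xi_n=xi0
        )
        res = transient_solve(groups, exch, traj, grid, initial_state=ic)
        ss = steady_state_with_nucleus(groups, exch, xi0, grid)
        assert abs(res.theta_n[-1] / ss.theta_n - 1.0) < 1e-4
        assert np.max(np.abs(res.theta_c_final / ss.theta_c - 1.0)) < 1e-4

    def test_mass_budget_closes(self, geometry, groups, exch, grid, rules):
        """Influx − degradation accounts for the change in total (cytoplasm +
        nucleus) mass; the exchange itself is exactly conservative."""
        traj = simulate_trajectory(geometry, groups, rules, seed=3,
                                   turning_position=0.8, pause_hours=0.5)
        res = transient_solve(groups, exch, traj, grid, dt=5e-3)
        assert res.diagnostics["mass_residual"] < 1e-10

    def test_positivity(self, geometry, groups, exch, grid, rules):
        traj = simulate_trajectory(geometry, groups, rules, seed=4,
                                   turning_position=0.9, pause_hours=0.2)
        res = transient_solve(groups, exch, traj, grid, dt=5e-3)
        assert res.theta_n.min() >= 0.0
        assert res.theta_c_final.min() >= 0.0

    def test_grid_convergence(self, groups, exch):
        """Halving dx changes the steady nuclear value by < 0.5%."""
        a = steady_state_with_nucleus(groups, exch, 0.4, Grid1D.make(125))
        b = steady_state_with_nucleus(groups, exch, 0.4, Grid1D.make(250))
        assert abs(a.theta_n / b.theta_n - 1.0) < 5e-3

    def test_oversized_dt_rejected_with_bound(self, geometry, groups, exch, grid, rules):
        traj = simulate_trajectory(geometry, groups, rules, seed=5,
                                   turning_position=0.5, pause_hours=0.1)
        bound = max_stable_dt(groups, exch)
        with pytest.raises(ValueError, match="maximum admissible dt"):
            transient_solve(groups, exch, traj, grid, dt=2 * bound)

    def test_instant_equilibrium_limit(self, geometry, transport, motion, exch, grid, rules):
        """×100 import/export: θ_n tracks (α_i/α_e) × footprint-averaged θ_c
        of the evolving field, and positional fluctuations pass through."""
        g0 = derive_dimensionless(geometry, transport, motion)
        traj = simulate_trajectory(geometry, g0, rules, seed=7,
                                   turning_position=0.9, pause_hours=1.0)
        g_hi = derive_dimensionless(geometry, scaled_exchange(transport, 100.0), motion)
        res = transient_solve(g_hi, exch, traj, grid, dt=1e-3, profile_stride=20)
        idx = np.searchsorted(res.times, res.profile_times)
        ratio = g_hi.alpha_i / g_hi.alpha_e
        devs = np.empty(len(idx))
        for k, i in enumerate(idx):
            w = footprint_weights(grid, float(res.xi_n[i]), exch.nuclear_extent)
            devs[k] = res.theta_n[i] - ratio * ((w / w.sum()) @ res.profiles[k])
        assert np.max(np.abs(devs)) / res.theta_n.max() < 0.02

    def test_low_exchange_limit_damps_everything(self, geometry, transport, motion, exch,
                                                 grid, rules):
        """×0.01 import/export: the nuclear level barely responds to a full
        traversal — far less than the ~100% swing at nominal rates."""
        g0 = derive_dimensionless(geometry, transport, motion)
        traj = simulate_trajectory(geometry, g0, rules, seed=7,
                                   turning_position=0.9, pause_hours=1.0)
        g_lo = derive_dimensionless(geometry, scaled_exchange(transport, 0.01), motion)
        res = transient_solve(g_lo, exch, traj, grid, dt=5e-3)
        variation = np.max(np.abs(res.theta_n - res.theta_n[0])) / res.theta_n[0]
        res_nom = transient_solve(g0, exch, traj, grid, dt=5e-3)
        swing_nom = (res_nom.theta_n.max() - res_nom.theta_n.min()) / res_nom.theta_n[0]
        assert variation < 0.2 * swing_nom

    def test_damping_of_pause_fluctuations(self, geometry, groups, exch, grid, rules):
        """Import/export kinetics low-pass the positional noise: per-step
        variability of θ_n during a pause is below that of the instantaneous
        equilibrium mapping of the same positions."""
        traj = simulate_trajectory(geometry, groups, rules, seed=11,
                                   turning_position=0.4, pause_hours=2.0)
        res = transient_solve(groups, exch, traj, grid, dt=5e-3)
        tr5 = resample_trajectory(traj, 5e-3)
        mask = tr5.phase == 1
        eq = (groups.alpha_i / groups.alpha_e) * footprint_average_map(
            groups, exch, grid, tr5.xi[mask]
        )
        actual = res.theta_n[mask[: len(res.theta_n)]]
        assert np.diff(actual).std() < np.diff(eq).std()
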