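"""Penalized Navier-Stokes solver: physics recovery and invariants."""

import numpy as np
import pytest

from aneuchip import (
    AneurysmParams,
    InletWaveform,
    PenalizedFlowSolver,
    SolverConfig,
    estimate_convergence_order,
    make_sidewall_aneurysm,
    make_straight_vessel,
    reynolds_number,
    solve_pulsatile,
    solve_steady,
)
from aneuchip.errors import UsageError
from aneuchip.solver import ConvergenceEstimate

D = 4.0e-3


class TestReynoldsNumber:
    def test_reference_conditions_give_about_250(self):
        re = reynolds_number(0.2, 4e-3, 3.25e-6)
        assert re == pytest.approx(246.15, rel=1e-3)
        assert abs(re - 250) / 250 < 0.02  # the conventional rounding

    def test_unit_inputs(self):
        assert reynolds_number(1, 1, 1) == 1.0

    def test_linearity_in_speed(self):
        assert reynolds_number(0.4, 4e-3, 3.25e-6) == pytest.approx(
            2 * reynolds_number(0.2, 4e-3, 3.25e-6))

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_nonpositive_arguments_rejected(self, args):
        with pytest.raises(UsageError):
            reynolds_number(*args)


class TestPoiseuilleRecovery:
    def test_centerline_speed_is_three_halves_mean(self, poiseuille_32):
        vel = poiseuille_32.cell_velocity()
        u_mid = vel[poiseuille_32.mask.shape[0] // 2, :, 0]
        assert u_mid.max() == pytest.approx(1.5, rel=0.02)

    def test_parabolic_profile_linf(self, poiseuille_32):
        sol = poiseuille_32
        mask = sol.mask
        vel = sol.cell_velocity()
        ix = mask.shape[0] // 2
        rows = np.flatnonzero(mask.fluid[ix])
        y = (rows + 0.5) * sol.h - rows.min() * sol.h  # 0 at lower wall face
        H = len(rows) * sol.h
        exact = 6.0 * (y / H) * (1.0 - y / H)
        err = np.abs(vel[ix, rows, 0] - exact).max() / exact.max()
        assert err < 0.02

    def test_steady_state_is_a_fixed_point_of_advance(self, poiseuille_32, channel_mask_32):
        solver = PenalizedFlowSolver(channel_mask_32, SolverConfig(reynolds=250.0))
        after = solver.step(poiseuille_32)
        change = max(np.abs(after.u - poiseuille_32.u).max(),
                     np.abs(after.v - poiseuille_32.v).max()) / solver.dt
        # residual rate stays at the steadiness tolerance it converged to
        assert change < 10 * 1e-7


class TestProjectionAndMass:
    def test_divergence_free_after_solve(self, poiseuille_32):
        assert poiseuille_32.max_fluid_divergence() < 1e-10

    def test_global_mass_balance(self, poiseuille_32):
        f_in, f_out = poiseuille_32.flux_balance()
        assert f_in == pytest.approx(1.0, rel=1e-12)  # discrete mean is exact
        assert abs(f_in - f_out) / f_in < 1e-6

    def test_divergence_invariant_every_step_from_random_field(self, channel_mask_32):
        solver = PenalizedFlowSolver(channel_mask_32, SolverConfig(reynolds=100.0))
        state = solver.initial_state()
        rng = np.random.default_rng(7)
        state.u = 0.1 * rng.standard_normal(state.u.shape)
        state.v = 0.1 * rng.standard_normal(state.v.shape)
        for _ in range(5):
            state = solver.step(state)
            assert state.max_fluid_divergence() < 1e-9

    def test_zero_inlet_zero_field_stays_zero(self, channel_mask_32):
        cfg = SolverConfig(reynolds=100.0, waveform=InletWaveform(mean=0.0))
        solver = PenalizedFlowSolver(channel_mask_32, cfg)
        state = solver.initial_state()
        for _ in range(3):
            state = solver.step(state)
        assert np.all(state.u == 0.0)
        assert np.all(state.v == 0.0)


class TestPenalizationLimit:
    def test_solid_speed_monotone_and_bounded_by_sqrt_eta(self, eta_sweep):
        etas = sorted(eta_sweep, reverse=True)  # 1e-4, 1e-6, 1e-8
        speeds = [eta_sweep[e].max_solid_speed() for e in etas]
        assert speeds[0] > speeds[1] > speeds[2] > 0
        # O(sqrt(eta)) upper envelope calibrated at the loosest eta
        c = speeds[0] / np.sqrt(etas[0])
        for eta, s in zip(etas, speeds):
            assert s <= 4.0 * c * np.sqrt(eta)


class TestSymmetry:
    def test_mirrored_geometry_gives_mirrored_flow(self):
        kw = dict(sac_radius=1.2e-3, neck_width=1.0e-3,
                  vessel_length=8e-3, sac_center_offset=4e-3)
        cfg = SolverConfig(reynolds=100.0, steady_tol=1e-7)
        top = solve_steady(make_sidewall_aneurysm(
            AneurysmParams(**kw), D / 24, wall_offset=0.2 * D,
            domain_height=2.2 * D), cfg)
        bottom = solve_steady(make_sidewall_aneurysm(
            AneurysmParams(sac_side="bottom", **kw), D / 24,
            wall_offset=0.2 * D, domain_height=2.2 * D), cfg)
        assert np.abs(top.u - bottom.u[:, ::-1]).max() < 1e-10
        assert np.abs(top.v + bottom.v[:, ::-1]).max() < 1e-10


@pytest.fixture(scope="module")
def pulsatile_solution():
    params = AneurysmParams(vessel_length=2 * D)
    mask = make_straight_vessel(params, D / 24, wall_offset=4 * (D / 24))
    wf = InletWaveform(amplitude=0.3, period=2.0)
    cfg = SolverConfig(reynolds=50.0, waveform=wf, max_steps=200_000)
    return solve_pulsatile(mask, cfg, n_periods=4, n_phases=8)


class TestPulsatile:

    def test_requires_pulsatile_waveform_and_enough_periods(self, channel_mask_32):
        cfg = SolverConfig(reynolds=50.0)
        with pytest.raises(UsageError):
            solve_pulsatile(channel_mask_32, cfg, n_periods=3, n_phases=4)
        wf = InletWaveform(amplitude=0.3, period=1.0)
        with pytest.raises(UsageError):
            solve_pulsatile(channel_mask_32, SolverConfig(reynolds=50.0, waveform=wf),
                            n_periods=1, n_phases=4)

    def test_final_period_is_quasi_periodic(self, pulsatile_solution):
        t0, u0, v0, _ = pulsatile_solution.history[0]
        t1, u1, v1, _ = pulsatile_solution.history[-1]
        assert t1 - t0 == pytest.approx(2.0, abs=2 * 5e-3)
        assert np.abs(u1 - u0).max() < 0.01  # 1% of the mean inlet speed

    def test_period_averaged_inlet_flux_matches_mean(self, pulsatile_solution):
        # integral of 1 + a sin(2 pi t / T) over a period is exactly T
        sol = pulsatile_solution
        rows = sol.mask.inlet_faces[:, 1]
        fluxes = [u[0, rows].sum() * sol.h for (_, u, _, _) in sol.history[:-1]]
        assert np.mean(fluxes) == pytest.approx(1.0, rel=0.02)

    def test_amplitude_to_zero_limit_matches_steady(self):
        params = AneurysmParams(vessel_length=2 * D)
        mask = make_straight_vessel(params, D / 16, wall_offset=3 * (D / 16))
        steady = solve_steady(mask, SolverConfig(reynolds=50.0, steady_tol=1e-8))
        wf = InletWaveform(amplitude=1e-4, period=2.0)
        puls = solve_pulsatile(mask, SolverConfig(reynolds=50.0, waveform=wf),
                               n_periods=4, n_phases=4)
        assert np.abs(puls.u - steady.u).max() < 0.01


class TestConvergenceOrder:
    def test_channel_triple_order_between_one_and_two(self, channel_triple):
        est = estimate_convergence_order(*channel_triple)
        assert not est.converged
        assert 1.0 <= est.order <= 2.1

    def test_identical_fields_signal_converged(self, channel_triple):
        from dataclasses import replace
        # constant copies of the triple: grid-independent fields must be
        # flagged "converged" instead of producing a spurious order
        consts = [replace(s, u=np.ones_like(s.u), v=np.zeros_like(s.v))
                  for s in channel_triple]
        est = estimate_convergence_order(*consts)
        assert est.converged and est.order is None

    def test_non_nested_grids_rejected(self, channel_triple):
        c, m, f = channel_triple
        with pytest.raises(UsageError):
            estimate_convergence_order(c, f, m)

    def test_discrete_operators_second_order_on_smooth_field(self):
        """Truncation order of the advective+diffusive operator on a
        manufactured smooth field, measured away from boundaries."""
        params = AneurysmParams(vessel_length=2 * D)
        results = []
        for n in (32, 64):
            mask = make_straight_vessel(params, D / n, wall_offset=0.25 * D)
            solver = PenalizedFlowSolver(mask, SolverConfig(reynolds=10.0))
            h = solver.h
            nx, ny = mask.shape
            xu, yu = np.meshgrid(np.arange(nx + 1) * h,
                                 (np.arange(ny) + 0.5) * h, indexing="ij")
            xv, yv = np.meshgrid((np.arange(nx) + 0.5) * h,
                                 np.arange(ny + 1) * h, indexing="ij")
            u = np.sin(xu) * np.cos(yu)
            v = -np.cos(xv) * np.sin(yv)  # divergence-free pair
            rhs_u, _ = solver._advect_diffuse(u, v)
            nu = solver.nu
            # -(d(u^2)/dx + d(uv)/dy) + nu lap(u) for the pair above
            exact = (-2.0 * np.sin(xu) * np.cos(xu) * np.cos(yu) ** 2
                     + np.sin(xu) * np.cos(xu) * np.cos(2.0 * yu)
                     - 2.0 * nu * np.sin(xu) * np.cos(yu))
            # compare deep inside the fluid, away from walls and ports
            sl = (slice(nx // 4, -nx // 4), slice(ny // 3, -ny // 3))
            results.append(np.abs(rhs_u - exact)[sl].max())
        order = np.log2(results[0] / results[1])
        assert order > 1.8


def test_instability_reported():
    from aneuchip.errors import NumericalError

    params = AneurysmParams(vessel_length=2 * D)
    mask = make_straight_vessel(params, D / 16, wall_offset=3 * (D / 16))
    # CFL = 1 with a fast transient is enough to break the explicit scheme
    cfg = SolverConfig(reynolds=5000.0, cfl=1.0, steady_tol=1e-14, max_steps=5000)
    with pytest.raises(NumericalError):
        solve_steady(mask, cfg)
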