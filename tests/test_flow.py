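import numpy as np
import pytest

from cochstream import (
    FlowNumerics,
    FluidProps,
    PeriodicFlowSolution,
    Stimulus,
    compute_drift,
    cross_section_flux,
    darcy_exchange,
    solve_oscillatory_flow,
    synthesize_wave,
    trace_particles,
)
from cochstream.flow import FlowConvergenceError


class TestDarcyExchange:
    def test_zero_pressure_difference(self):
        assert darcy_exchange(0.0, 1.0) == 0.0

    def test_linear_formula_and_sign(self):
        # dp = p_corti - p_scala = -3 Pa drives flow into the Corti duct
        assert darcy_exchange(-3.0, 1.0) == pytest.approx(3.0)

    def test_impermeable_limit(self):
        assert darcy_exchange(123.4, 0.0) == 0.0

    def test_negative_permeability_rejected(self):
        with pytest.raises(ValueError):
            darcy_exchange(1.0, -0.1)


def _synthetic_solution(u_t_fn, nx=6, ny=4, n_samp=64, omega=2 * np.pi * 1000.0):
    """Analytic Eulerian samples for drift-averaging tests."""
    dt = (2 * np.pi / omega) / n_samp
    ts = dt * np.arange(1, n_samp + 1)
    u = np.array([np.full((nx + 1, ny), u_t_fn(t)) for t in ts])
    v = np.zeros((n_samp, nx, ny + 1))
    return PeriodicFlowSolution(
        x_faces=np.linspace(0, 1e-3, nx + 1),
        y_faces=np.linspace(0, 1e-4, ny + 1),
        membrane_index=2,
        omega=omega,
        dt=dt,
        t_samples=ts,
        u=u,
        v=v,
        p=np.zeros((n_samp, nx, ny)),
        membrane_exchange=None,
        wall_velocity_top=np.zeros((n_samp, nx)),
        wall_velocity_membrane=None,
        residual_history=[1e-9],
        periodicity_residual=1e-9,
        fluid=FluidProps(),
    )


class TestDriftAveraging:
    def test_pure_oscillation_averages_to_zero(self):
        omega = 2 * np.pi * 1000.0
        sol = _synthetic_solution(lambda t: 0.01 * np.cos(omega * t), omega=omega)
        drift = compute_drift(sol)
        assert np.max(np.abs(drift.u)) < 1e-16

    def test_steady_component_is_preserved(self):
        sol = _synthetic_solution(lambda t: 3.7e-4)
        drift = compute_drift(sol)
        np.testing.assert_allclose(drift.u, 3.7e-4)

    def test_nonperiodic_solution_rejected(self):
        sol = _synthetic_solution(lambda t: 1.0)
        sol.periodicity_residual = 0.5
        with pytest.raises(ValueError, match="periodic"):
            compute_drift(sol)


class TestCrossSectionFlux:
    def test_zero_field_zero_flux(self):
        drift = compute_drift(_synthetic_solution(lambda t: 0.0))
        assert cross_section_flux(drift, 5e-4, "both") == 0.0

    def test_out_of_domain_rejected(self):
        drift = compute_drift(_synthetic_solution(lambda t: 0.0))
        with pytest.raises(ValueError):
            cross_section_flux(drift, 2e-3)

    def test_layers_partition_the_section(self):
        drift = compute_drift(_synthetic_solution(lambda t: 1e-3))
        both = cross_section_flux(drift, 5e-4, "both")
        parts = cross_section_flux(drift, 5e-4, "corti") + cross_section_flux(
            drift, 5e-4, "scala"
        )
        assert both == pytest.approx(parts)


class TestParticleTracing:
    def test_zero_field_keeps_particles_still(self):
        sol = _synthetic_solution(lambda t: 0.0)
        traj, mean_v, trunc = trace_particles(sol, [[5e-4, 5e-5]], n_periods=2)
        assert np.allclose(traj[0, 0], traj[0, -1])
        assert not trunc[0]

    def test_uniform_field_displaces_by_u_t(self):
        sol = _synthetic_solution(lambda t: 1e-3)
        T = sol.period_s
        traj, mean_v, _ = trace_particles(sol, [[1e-4, 5e-5]], n_periods=1)
        assert traj[0, -1, 0] - traj[0, 0, 0] == pytest.approx(1e-3 * T, rel=1e-6)
        assert mean_v[0, 0] == pytest.approx(1e-3, rel=1e-6)

    def test_lagrangian_drift_sign_matches_eulerian(
        self, small_active_solution, small_active_drift
    ):
        # seed a tracer where the Corti-duct drift is strongest
        drift = small_active_drift
        jm = drift.membrane_index
        uc = 0.5 * (drift.u[:-1, jm:] + drift.u[1:, jm:])
        i, j = np.unravel_index(np.argmax(np.abs(uc)), uc.shape)
        x0 = (i + 0.5) * drift.dx
        y0 = (jm + j + 0.5) * drift.dy
        _, mean_v, _ = trace_particles(small_active_solution, [[x0, y0]], n_periods=4)
        assert np.sign(mean_v[0, 0]) == np.sign(uc[i, j])


class TestCochlearFlow:
    def test_silence_produces_no_flow(self, small_geom):
        wave = synthesize_wave(small_geom, Stimulus(kind="silence"))
        sol = solve_oscillatory_flow(
            small_geom, wave, numerics=FlowNumerics(max_periods=5)
        )
        assert np.max(np.abs(sol.u)) < 1e-16
        assert np.ptp(sol.p) < 1e-12

    def test_interior_divergence_free(self, small_active_solution):
        # continuity: discrete divergence at solver precision, scaled by u/dx
        scale = small_active_solution.peak_oscillatory_speed() / small_active_solution.dx
        assert small_active_solution.max_divergence() < 1e-10 * scale

    def test_periodic_steady_state_reached(self, small_active_solution):
        assert small_active_solution.periodicity_residual < 1e-4

    def test_closed_domain_net_drift_flux_vanishes(self, small_active_drift):
        drift = small_active_drift
        peak_flux = max(
            abs(cross_section_flux(drift, x, "corti"))
            for x in np.linspace(1e-3, 11e-3, 21)
        )
        for x in np.linspace(1e-3, 11e-3, 21):
            assert abs(cross_section_flux(drift, x, "both")) < 1e-8 * peak_flux

    def test_unresolved_stokes_layer_rejected(self):
        from cochstream import CochlearGeometry

        coarse = CochlearGeometry(
            h_corti_m=80e-6, ny_corti=4, h_scala_m=200e-6, ny_scala=10, nx=40
        )
        wave = synthesize_wave(coarse, Stimulus(kind="tone", frequency_hz=1000.0))
        with pytest.raises(ValueError, match="Stokes layer"):
            solve_oscillatory_flow(coarse, wave)

    def test_nonconvergence_reports_residual_history(self, small_geom):
        wave = synthesize_wave(
            small_geom, Stimulus(kind="tone", frequency_hz=1000.0, level_db_spl=80.0)
        )
        with pytest.raises(FlowConvergenceError) as exc:
            solve_oscillatory_flow(
                small_geom,
                wave,
                numerics=FlowNumerics(
                    max_periods=3, min_periods=2, periodicity_tol=1e-16
                ),
            )
        assert len(exc.value.residual_history) >= 1
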