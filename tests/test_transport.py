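import numpy as np
import pytest

from cochstream import (
    CochlearGeometry,
    DriftField,
    TransportBC,
    TransportNumerics,
    diffusion_1d_closed_form,
    effect_time_1d,
    effect_time_map,
    solve_transport,
)

D = 1e-9
C0 = 10.0


@pytest.fixture(scope="module")
def thin_geom():
    """Two thin layers; with a full basal-face source the problem is 1-D in x."""
    return CochlearGeometry(
        length_m=12e-3, h_corti_m=40e-6, h_scala_m=40e-6,
        ny_corti=2, ny_scala=2, nx=600,
    )


@pytest.fixture(scope="module")
def diffusion_series(thin_geom):
    return solve_transport(
        thin_geom,
        None,
        D,
        TransportBC(source_mode="basal_face"),
        t_end_s=2000.0,
        output_times_s=np.geomspace(5.0, 2000.0, 50),
    )


class TestClosedForm:
    def test_source_value_at_origin(self):
        assert diffusion_1d_closed_form(0.0, 10.0, D, C0) == pytest.approx(C0)

    def test_long_time_limit_saturates(self):
        assert diffusion_1d_closed_form(1e-3, 1e16, D, C0) == pytest.approx(
            C0, rel=1e-6
        )

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            diffusion_1d_closed_form(1e-3, 0.0, D, C0)

    def test_threshold_inversion_matches_brute_force_scan(self):
        # the closed-form crossing time equals the one found by scanning C(t)
        x = 4e-3
        t_scan = np.geomspace(1.0, 1e5, 400000)
        c = diffusion_1d_closed_form(x, t_scan, D, C0)
        i = np.argmax(c >= 0.01 * C0)
        t_bruteforce = t_scan[i]
        assert effect_time_1d(x, D, 0.01) == pytest.approx(t_bruteforce, rel=1e-3)


class TestTransportSolver:
    def test_saturated_state_is_steady(self, thin_geom):
        c_init = np.full((thin_geom.nx, thin_geom.ny), C0)
        ser = solve_transport(
            thin_geom, None, D, TransportBC(source_mode="basal_face"),
            t_end_s=100.0, output_times_s=[50.0, 100.0], c_init=c_init,
        )
        np.testing.assert_allclose(ser.c, C0, rtol=1e-9)

    def test_matches_erfc_profile(self, thin_geom, diffusion_series):
        # coarse check; the strict 2% comparison runs in the acceptance suite
        k = np.argmin(np.abs(diffusion_series.times_s - 1000.0))
        t = diffusion_series.times_s[k]
        ref = diffusion_1d_closed_form(thin_geom.x_centers, t, D, C0)
        m = ref >= 0.01 * C0
        err = np.abs(diffusion_series.c[k, :, 1][m] - ref[m]) / ref[m]
        assert np.max(err) < 0.05

    def test_bounds_and_monotonicity(self, diffusion_series):
        c = diffusion_series.c
        assert c.min() >= 0.0
        assert c.max() <= C0 * (1 + 1e-9)
        # constant source, zero initial data: concentrations only rise
        assert np.all(np.diff(c, axis=0) >= -1e-9 * C0)

    def test_mass_balance_within_half_percent(self, diffusion_series):
        assert diffusion_series.max_balance_error() < 5e-3

    def test_gaussian_pulse_translates_with_uniform_drift(self, thin_geom):
        U = 1e-4
        nx, ny = thin_geom.nx, thin_geom.ny
        drift = DriftField(
            x_faces=thin_geom.x_faces, y_faces=thin_geom.y_faces,
            membrane_index=thin_geom.membrane_index,
            u=np.full((nx + 1, ny), U), v=np.zeros((nx, ny + 1)),
            omega=2 * np.pi * 1000.0, peak_oscillatory_speed=1.0,
        )
        x = thin_geom.x_centers
        c0 = np.tile(np.exp(-(((x - 3e-3) / 0.3e-3) ** 2))[:, None], (1, ny))
        ser = solve_transport(
            thin_geom, drift, 1e-11, TransportBC(source_mode="none"),
            t_end_s=20.0, output_times_s=[20.0],
            numerics=TransportNumerics(dt0_s=0.01, growth=1.05, time_scheme="be"),
            c_init=c0,
        )
        c = ser.c[0]
        mass_ratio = c.sum() / c0.sum()
        centroid = float((c.sum(axis=1) * x).sum() / c.sum())
        assert mass_ratio == pytest.approx(1.0, abs=5e-3)
        assert centroid == pytest.approx(3e-3 + U * 20.0, abs=thin_geom.dx)

    def test_central_scheme_refuses_peclet_violating_mesh(self, thin_geom):
        nx, ny = thin_geom.nx, thin_geom.ny
        drift = DriftField(
            x_faces=thin_geom.x_faces, y_faces=thin_geom.y_faces,
            membrane_index=thin_geom.membrane_index,
            u=np.full((nx + 1, ny), 1e-3), v=np.zeros((nx, ny + 1)),
            omega=2 * np.pi * 1000.0, peak_oscillatory_speed=1.0,
        )
        with pytest.raises(ValueError, match="Peclet"):
            solve_transport(
                thin_geom, drift, D, TransportBC(source_mode="basal_face"),
                t_end_s=10.0, output_times_s=[10.0],
                numerics=TransportNumerics(scheme="central"),
            )

    def test_mismatched_drift_grid_rejected(self, thin_geom):
        drift = DriftField(
            x_faces=np.linspace(0, 1e-3, 11), y_faces=np.linspace(0, 1e-4, 5),
            membrane_index=2, u=np.zeros((11, 4)), v=np.zeros((10, 5)),
            omega=1.0, peak_oscillatory_speed=0.0,
        )
        with pytest.raises(ValueError, match="grid"):
            solve_transport(thin_geom, drift, D)


class TestEffectTimeMap:
    def test_source_region_reached_immediately(self, diffusion_series):
        prof = effect_time_map(diffusion_series)
        assert prof.reached[0]
        assert prof.te_s[0] <= diffusion_series.times_s[0]

    def test_pure_diffusion_matches_closed_form_inversion(
        self, thin_geom, diffusion_series
    ):
        prof = effect_time_map(diffusion_series)
        ref = effect_time_1d(thin_geom.x_centers, D, 0.01)
        m = prof.reached & (thin_geom.x_centers > 0.3e-3) & (ref > diffusion_series.times_s[0])
        rel = np.abs(prof.te_s[m] - ref[m]) / ref[m]
        assert np.max(rel) < 0.03

    def test_unreached_places_marked(self, diffusion_series):
        prof = effect_time_map(diffusion_series)
        assert not prof.reached[-1]
        assert np.isnan(prof.te_s[-1])

    def test_default_threshold_is_one_percent_of_source(self, diffusion_series):
        # 10 mM source => 100 uM threshold
        prof = effect_time_map(diffusion_series)
        assert prof.threshold_mol_m3 == pytest.approx(0.1)

    def test_monotone_in_distance_under_pure_diffusion(self, diffusion_series):
        prof = effect_time_map(diffusion_series)
        te = prof.te_s[prof.reached]
        assert np.all(np.diff(te) >= 0)
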