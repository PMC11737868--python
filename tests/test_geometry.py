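import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cochstream import (
    CochlearGeometry,
    Stimulus,
    WaveParams,
    build_geometry,
    cf_from_place,
    place_from_cf,
    synthesize_wave,
    wall_kinematics,
)
from cochstream.geometry import geometry_to_yaml


class TestGeometryConstruction:
    def test_default_length_is_gerbil_cochlea(self, geom):
        assert geom.length_m == pytest.approx(0.012)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"h_corti_m": 0.0}, "h_corti_m"),
            ({"h_scala_m": -1e-6}, "h_scala_m"),
            ({"length_m": 0.0}, "length_m"),
        ],
    )
    def test_nonpositive_dimension_rejected_by_name(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            CochlearGeometry(**kwargs)

    def test_mismatched_cell_heights_rejected(self):
        with pytest.raises(ValueError, match="uniform dy"):
            CochlearGeometry(h_corti_m=80e-6, ny_corti=8, h_scala_m=500e-6, ny_scala=13)

    def test_yaml_round_trip_is_identity(self, geom):
        rebuilt = build_geometry(geometry_to_yaml(geom))
        assert rebuilt == geom

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_geometry({"geometry": {"length_m": 0.012, "bogus": 1}})


class TestPlaceFrequencyMap:
    def test_tonotopy_direction(self, geom):
        assert cf_from_place(geom, 0.0) > cf_from_place(geom, geom.length_m)

    def test_cf_strictly_decreasing_on_dense_grid(self, geom):
        # exhaustive scan over a 1000-point grid
        x = np.linspace(0, geom.length_m, 1000)
        cf = cf_from_place(geom, x)
        assert np.all(np.diff(cf) < 0)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=0.0, max_value=0.012))
    def test_map_inverse_identity(self, x):
        geom = CochlearGeometry()
        assert place_from_cf(geom, cf_from_place(geom, x)) == pytest.approx(
            x, abs=1e-12
        )

    def test_out_of_range_inputs_raise(self, geom):
        with pytest.raises(ValueError):
            cf_from_place(geom, geom.length_m * 1.5)
        with pytest.raises(ValueError):
            place_from_cf(geom, 1e9)


class TestTravelingWaveSurrogate:
    def test_peak_at_tonotopic_place(self, geom):
        stim = Stimulus(kind="tone", frequency_hz=1000.0, level_db_spl=80.0)
        wave = synthesize_wave(geom, stim)
        assert wave.x_peak_m == pytest.approx(place_from_cf(geom, 1000.0))
        i_peak = np.argmax(wave.amp_bottom_m)
        assert abs(wave.x_m[i_peak] - wave.x_peak_m) < 2 * geom.dx

    def test_active_mode_has_area_differential_in_tail(self, geom):
        stim = Stimulus(kind="tone", frequency_hz=1000.0, level_db_spl=80.0)
        wave = synthesize_wave(geom, stim, ohc_active=True)
        tail = (wave.x_m > wave.x_peak_m - 2e-3) & (wave.x_m < wave.x_peak_m)
        assert np.any(wave.amp_top_m[tail] != wave.amp_bottom_m[tail])

    def test_passive_mode_zero_area_change(self, geom):
        stim = Stimulus(kind="tone", frequency_hz=1000.0, level_db_spl=80.0)
        wave = synthesize_wave(geom, stim, ohc_active=False)
        np.testing.assert_array_equal(wave.amp_top_m, wave.amp_bottom_m)
        np.testing.assert_array_equal(wave.phase_offset_rad, 0.0)

    def test_silence_gives_zero_amplitudes(self, geom):
        wave = synthesize_wave(geom, Stimulus(kind="silence"))
        assert np.all(wave.amp_bottom_m == 0) and np.all(wave.amp_top_m == 0)

    def test_amplitude_linear_in_pressure(self, geom):
        # doubling the stimulus pressure (+6.0206 dB) doubles the amplitude
        s1 = Stimulus(kind="tone", frequency_hz=2000.0, level_db_spl=60.0)
        s2 = Stimulus(
            kind="tone", frequency_hz=2000.0, level_db_spl=60.0 + 20 * np.log10(2)
        )
        x = np.linspace(1e-4, 0.0119, 50)
        w1 = synthesize_wave(geom, s1, x_m=x)
        w2 = synthesize_wave(geom, s2, x_m=x)
        np.testing.assert_allclose(w2.amp_bottom_m, 2 * w1.amp_bottom_m, rtol=1e-12)

    def test_phase_lag_nondecreasing(self, geom):
        wave = synthesize_wave(geom, Stimulus(kind="tone", frequency_hz=4000.0))
        assert np.all(np.diff(wave.phase_rad) >= 0)

    def test_envelope_support_ends_past_cutoff(self, geom):
        p = WaveParams()
        wave = synthesize_wave(geom, Stimulus(kind="tone", frequency_hz=4000.0), params=p)
        far = wave.x_m > wave.x_peak_m + 3 * p.cutoff_len_m
        assert np.all(wave.amp_bottom_m[far] < 1e-3 * wave.amp_bottom_m.max())

    def test_frequency_outside_map_raises(self, geom):
        with pytest.raises(ValueError):
            synthesize_wave(geom, Stimulus(kind="tone", frequency_hz=1e6))

    def test_broadband_must_be_decomposed(self, geom):
        stim = Stimulus(kind="broadband", band_hz=(100.0, 12000.0))
        with pytest.raises(ValueError, match="decomposed"):
            synthesize_wave(geom, stim)


@pytest.fixture(scope="module")
def wave():
    geom = CochlearGeometry()
    return synthesize_wave(
        geom, Stimulus(kind="tone", frequency_hz=1000.0, level_db_spl=80.0)
    )


class TestWallKinematics:
    def test_zero_amplitude_wave_is_still(self):
        geom = CochlearGeometry()
        wave = synthesize_wave(geom, Stimulus(kind="silence"))
        d, v = wall_kinematics(wave, "bottom", 5e-3, 1.23e-3)
        assert d == 0.0 and v == 0.0

    def test_periodicity(self, wave):
        T = wave.period_s
        x = 7e-3
        d1, v1 = wall_kinematics(wave, "top", x, 0.4e-3)
        d2, v2 = wall_kinematics(wave, "top", x, 0.4e-3 + T)
        assert d1 == pytest.approx(d2, rel=1e-9)
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_velocity_is_time_derivative(self, wave):
        # central finite difference of displacement converges at O(dt^2)
        x, t = 7.5e-3, 0.3e-3
        errs = []
        for dt in (1e-6, 5e-7):
            dp, _ = wall_kinematics(wave, "bottom", x, t + dt)
            dm, _ = wall_kinematics(wave, "bottom", x, t - dt)
            _, v = wall_kinematics(wave, "bottom", x, t)
            errs.append(abs((dp - dm) / (2 * dt) - v))
        assert errs[1] < errs[0] / 3.0  # ~4x reduction expected

    def test_unknown_surface_rejected(self, wave):
        with pytest.raises(ValueError, match="surface"):
            wall_kinematics(wave, "side", 1e-3, 0.0)

    def test_negative_time_rejected(self, wave):
        with pytest.raises(ValueError):
            wall_kinematics(wave, "top", 1e-3, -1.0)
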