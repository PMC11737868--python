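import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cochstream import (
    NeuralResponseSeries,
    SampledSignal,
    average_presentations,
    dpoae_change,
    dpoae_level_track,
    dpoae_noise_floor,
    driven_response,
    effect_time,
    gen_dpoae_sweep,
    teager_transform,
)


class TestTeagerTransform:
    def test_constant_signal_maps_to_zero(self):
        out = teager_transform(SampledSignal(np.full(100, 3.3), 1e4))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_zero_signal_maps_to_zero(self):
        out = teager_transform(SampledSignal(np.zeros(50), 1e4))
        assert np.all(out.samples == 0)

    def test_output_two_samples_shorter(self):
        out = teager_transform(SampledSignal(np.arange(10.0), 1e4))
        assert out.samples.size == 8

    def test_sinusoid_closed_form(self):
        # brute-force evaluation of psi[n] on a sinusoid equals A^2 sin^2(Omega)
        A, Om, ph = 1.7, 0.4, 0.3
        x = A * np.sin(Om * np.arange(200) + ph)
        brute = np.array(
            [x[n] ** 2 - x[n - 1] * x[n + 1] for n in range(1, 199)]
        )
        out = teager_transform(SampledSignal(x, 1e4)).samples
        np.testing.assert_allclose(out, brute, atol=1e-14)
        np.testing.assert_allclose(out, A**2 * np.sin(Om) ** 2, atol=1e-12)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            teager_transform(SampledSignal(np.array([1.0, 2.0]), 1e4))

    @settings(max_examples=60, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=1.5),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.0, max_value=6.28),
    )
    def test_nonnegative_for_slow_sinusoids(self, omega, amp, phase):
        x = amp * np.sin(omega * np.arange(64) + phase)
        out = teager_transform(SampledSignal(x, 1e4)).samples
        assert np.all(out >= -1e-12 * amp**2)


class TestDrivenResponse:
    @pytest.mark.parametrize(
        "tone, spont, expected", [(5.0, 2.0, 3.0), (2.0, 2.0, 0.0), (1.0, 4.0, 0.0)]
    )
    def test_difference_floored_at_zero(self, tone, spont, expected):
        assert driven_response(tone, spont) == expected

    def test_flooring_flagged(self):
        val, floored = driven_response(1.0, 4.0, with_flag=True)
        assert val == 0.0 and floored
        _, ok = driven_response(4.0, 1.0, with_flag=True)
        assert not ok

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            driven_response(-1.0, 0.0)


def _sigmoid_series(te_min, tau=3.0, dt_min=57.2 / 60.0, noise=None, rng=None):
    t = np.arange(-10.0, 120.0, dt_min)
    t0 = te_min - tau * np.log((1 - 0.75) / 0.75)
    r = 1.0 / (1.0 + np.exp((t - t0) / tau))
    if noise:
        r = r * (1 + noise * rng.standard_normal(r.size))
    return NeuralResponseSeries(t, r, cf_hz=3800.0, condition="silence", normalized=True)


class TestEffectTime:
    def test_known_crossing_at_54_minutes(self):
        # pure logistic with its 75% crossing constructed at 54 min
        ser = _sigmoid_series(54.0)
        assert effect_time(ser) == pytest.approx(54.0, abs=57.2 / 60.0)

    def test_flat_curve_unreached(self):
        t = np.arange(-10.0, 60.0, 1.0)
        ser = NeuralResponseSeries(t, np.ones_like(t), 3800.0, "silence", normalized=True)
        assert np.isnan(effect_time(ser))

    def test_crossing_recovered_within_sample_interval(self):
        # dense brute-force scan of the noiseless curve brackets the estimate
        for te in (12.3, 54.0, 101.7):
            ser = _sigmoid_series(te)
            t_dense = np.linspace(-10, 120, 2000001)
            tau, t0 = 3.0, te - 3.0 * np.log((1 - 0.75) / 0.75)
            r_dense = 1.0 / (1.0 + np.exp((t_dense - t0) / tau))
            brute = t_dense[np.argmax(r_dense < 0.75)]
            assert effect_time(ser) == pytest.approx(brute, abs=57.2 / 60.0)

    def test_uniform_delay_shifts_effect_time(self):
        t1 = effect_time(_sigmoid_series(40.0))
        t2 = effect_time(_sigmoid_series(55.0))
        assert t2 - t1 == pytest.approx(15.0, abs=0.2)

    def test_sustained_rule_rejects_single_noise_dip(self):
        t = np.arange(-5.0, 60.0, 1.0)
        r = np.ones_like(t)
        r[20] = 0.5  # one-sample artifact
        ser = NeuralResponseSeries(t, r, 3800.0, "silence", normalized=True)
        assert np.isnan(effect_time(ser, sustain=3))
        assert np.isfinite(effect_time(ser, sustain=1))

    def test_unnormalized_series_needs_baseline(self):
        t = np.arange(0.0, 60.0, 1.0)  # no samples before application
        ser = NeuralResponseSeries(t, np.ones_like(t), 3800.0, "silence")
        with pytest.raises(ValueError, match="baseline"):
            effect_time(ser)


@pytest.fixture(scope="module")
def clean_sweeps():
    return gen_dpoae_sweep(20.0, 65.0, noise_db_spl=-30.0, n_presentations=4, seed=7)


class TestDPOAE:
    def test_embedded_dp_level_recovered(self, clean_sweeps):
        f, lv = dpoae_level_track(average_presentations(clean_sweeps))
        interior = (f > 400) & (f < 5500)
        assert np.all(np.abs(lv[interior] - 20.0) < 1.0)

    def test_frequency_bookkeeping(self, clean_sweeps):
        # where f1 = 4 kHz (f2 = 5 kHz), the DP frequency is 2*4 - 5 = 3 kHz
        f, _ = dpoae_level_track(average_presentations(clean_sweeps))
        assert np.min(np.abs(f - 3000.0)) < 30.0
        assert f.max() < 0.6 * 10000.0 + 1.0  # fdp = 0.6 f2 throughout

    def test_no_dp_component_tracks_at_floor(self):
        sweeps = gen_dpoae_sweep(-np.inf, 65.0, noise_db_spl=-30.0,
                                 n_presentations=2, seed=1)
        f, lv = dpoae_level_track(average_presentations(sweeps))
        assert np.median(lv) < -30.0

    def test_identical_presentations_null_floor(self, clean_sweeps):
        same = [clean_sweeps[0], clean_sweeps[0]]
        _, floor = dpoae_noise_floor(same)
        assert np.all(floor <= -300.0)  # numerical zero, capped

    def test_floor_invariant_to_deterministic_component(self, clean_sweeps):
        _, floor0 = dpoae_noise_floor(clean_sweeps)
        boosted = []
        for s in clean_sweeps:
            w = s.waveform + 0.5 * np.sin(
                2 * np.pi * 700.0 * np.arange(s.waveform.size) / s.fs_hz
            )
            boosted.append(type(s)(waveform=w, fs_hz=s.fs_hz))
        _, floor1 = dpoae_noise_floor(boosted)
        np.testing.assert_allclose(floor1, floor0, atol=1e-6)

    def test_window_longer_than_sweep_rejected(self, clean_sweeps):
        with pytest.raises(ValueError, match="window"):
            dpoae_level_track(clean_sweeps[0], window_s=10.0)

    def test_fewer_than_two_presentations_rejected(self, clean_sweeps):
        with pytest.raises(ValueError):
            dpoae_noise_floor(clean_sweeps[:1])


class TestDPOAEChange:
    def _track(self, level):
        f = np.linspace(300, 6000, 50)
        return f, np.full(50, level)

    def test_identical_tracks_not_excluded(self):
        d, excl = dpoae_change(self._track(10.0), self._track(10.0))
        assert d == 0.0 and not excl

    def test_six_db_drop_excluded(self):
        d, excl = dpoae_change(self._track(10.0), self._track(4.0))
        assert d == pytest.approx(6.0) and excl

    def test_exactly_five_db_kept(self):
        # the exclusion rule is 'more than 5 dB'
        d, excl = dpoae_change(self._track(10.0), self._track(5.0))
        assert d == pytest.approx(5.0) and not excl

    def test_disjoint_grids_rejected(self):
        f1 = np.linspace(300, 6000, 50)
        f2 = np.linspace(300, 6000, 60)
        with pytest.raises(ValueError, match="grid"):
            dpoae_change((f1, np.zeros(50)), (f2, np.zeros(60)))
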