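"""Synthetic inputs with known ground truth for every analysis stage.

Generators for: normalized neural-response decay curves (unimodal or bimodal
logistic with multiplicative noise, sampled on the 57.2 s stimulus-sequence
grid), effect-time cohorts following the 1-D diffusion trend with
per-condition facilitation offsets in dB and lognormal scatter, spike-like
multiunit waveforms for the Teager/driven-response chain, and swept two-tone
DPOAE presentations with an embedded 2f1-f2 component of known level.

All generators are deterministic under a fixed seed.  When the noise is
switched off they satisfy the downstream analysis model exactly, closing the
loop between generator and estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .geometry import CochlearGeometry, place_from_cf
from .neural import DPOAESweep, NeuralResponseSeries, SampledSignal, P_REF_PA
from .transport import effect_time_1d

__all__ = [
    "CurveSpec",
    "CohortSpec",
    "DEFAULT_CONDITION_OFFSETS_DB",
    "gen_response_curve",
    "gen_cohort",
    "gen_spike_signal",
    "gen_dpoae_sweep",
]

#: facilitation offsets (dB re the silence trend) below/above the CF split,
#: qualitatively mirroring the measured pattern: broadband sound and the
#: mid-frequency tone act at high-CF (basal) places, the low-frequency tone
#: acts everywhere, and salicylate pre-treatment abolishes the sound effect.
DEFAULT_CONDITION_OFFSETS_DB = {
    "silence": (0.0, 0.0),
    "sound": (0.0, -6.0),
    "post_SA": (0.0, 0.0),
    "LF_tone": (-8.0, -5.0),
    "MF_tone": (0.0, -6.0),
}


@dataclass(frozen=True)
class CurveSpec:
    """Ground truth for one synthetic response curve.

    The noiseless 75%-of-baseline crossing sits exactly at ``te_min``.
    ``sample_interval_s`` defaults to the 57.2 s stimulus sequence (51 pips
    plus a pause).  A bimodal curve first decays to ``plateau`` and completes
    the decay ``second_drop_delay_min`` later.
    """

    te_min: float = 54.0
    tau_min: float = 4.0
    threshold: float = 0.75
    floor: float = 0.02
    bimodal: bool = False
    plateau: float = 0.5
    second_drop_delay_min: float = 30.0
    sample_interval_s: float = 57.2
    t_start_min: float = -10.0
    t_end_min: float = 150.0
    noise_sigma: float = 0.05
    cf_hz: float = 3800.0
    condition: str = "silence"
    seed: int = 0

    def __post_init__(self):
        if not self.sample_interval_s > 0:
            raise ValueError("sample_interval_s must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.bimodal and not (self.floor < self.plateau < self.threshold < 1):
            raise ValueError("bimodal curve needs floor < plateau < threshold")


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def gen_response_curve(spec: CurveSpec) -> NeuralResponseSeries:
    """Synthesize a normalized response curve with a known effect time."""
    rng = np.random.default_rng(spec.seed)
    dt = spec.sample_interval_s / 60.0
    t = np.arange(spec.t_start_min, spec.t_end_min + dt / 2, dt)

    if spec.bimodal:
        # first drop 1 -> plateau carries the threshold crossing
        amp1 = 1.0 - spec.plateau
        t0 = spec.te_min - spec.tau_min * np.log(
            amp1 / (spec.threshold - spec.plateau) - 1.0
        )
        t1 = spec.te_min + spec.second_drop_delay_min
        r = (
            spec.floor
            + (spec.plateau - spec.floor) * _logistic(-(t - t1) / spec.tau_min)
            + amp1 * _logistic(-(t - t0) / spec.tau_min)
        )
    else:
        amp = 1.0 - spec.floor
        t0 = spec.te_min - spec.tau_min * np.log(
            amp / (spec.threshold - spec.floor) - 1.0
        )
        r = spec.floor + amp * _logistic(-(t - t0) / spec.tau_min)
    # pin the pre-application baseline at 1 (probe tones before delivery)
    r[t < 0] = 1.0
    if spec.noise_sigma > 0:
        r = r * (1.0 + spec.noise_sigma * rng.standard_normal(r.shape))
    return NeuralResponseSeries(
        t_min=t,
        response=r,
        cf_hz=spec.cf_hz,
        condition=spec.condition,
        normalized=True,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of an effect-time cohort.

    Effect times follow the 1-D diffusion trend
    ``tE = x^2 / (4 D_eff z^2)`` (z = erfcinv(threshold_fraction)) times a
    condition offset and lognormal noise:
    ``tE = tTrend(x) * 10**((offset + eps)/20)``, ``eps ~ N(0, sigma_db^2)``.
    Characteristic frequencies are drawn log-uniformly over ``cf_range_hz``;
    places follow from the tonotopic map of ``geometry``.
    """

    n_per_condition: dict = field(
        default_factory=lambda: {"silence": 48, "sound": 34}
    )
    d_eff_m2_s: float = 1.0e-9
    threshold_fraction: float = 0.01
    sigma_db: float = 3.0
    offsets_db: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_OFFSETS_DB)
    )
    cf_range_hz: tuple = (1000.0, 20000.0)
    cf_split_hz: float = 4500.0
    records_per_animal: int = 3
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.n_per_condition.values()):
            raise ValueError("record counts must be positive")
        if self.sigma_db < 0:
            raise ValueError("sigma_db must be non-negative")
        if not self.d_eff_m2_s > 0:
            raise ValueError("d_eff_m2_s must be positive")


def gen_cohort(spec: CohortSpec, geometry: CochlearGeometry | None = None) -> pd.DataFrame:
    """Draw an effect-time cohort as a records table.

    Columns: ``animal_id, cf_hz, place_m, condition, te_min``.
    """
    geom = geometry or CochlearGeometry()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond, n in spec.n_per_condition.items():
        off_low, off_high = spec.offsets_db.get(cond, (0.0, 0.0))
        cf = np.exp(
            rng.uniform(np.log(spec.cf_range_hz[0]), np.log(spec.cf_range_hz[1]), n)
        )
        x = np.asarray(place_from_cf(geom, cf))
        trend_min = effect_time_1d(x, spec.d_eff_m2_s, spec.threshold_fraction) / 60.0
        offset = np.where(cf > spec.cf_split_hz, off_high, off_low)
        eps = spec.sigma_db * rng.standard_normal(n)
        te = trend_min * 10.0 ** ((offset + eps) / 20.0)
        for i in range(n):
            rows.append(
                {
                    "animal_id": f"{cond[:2].upper()}{i // spec.records_per_animal:03d}",
                    "cf_hz": float(cf[i]),
                    "place_m": float(x[i]),
                    "condition": cond,
                    "te_min": float(te[i]),
                }
            )
    return pd.DataFrame(rows)


def gen_spike_signal(
    rate_hz: float,
    tone_locked_fraction: float = 0.5,
    fs_hz: float = 50000.0,
    duration_s: float = 1.0,
    snr: float = 3.0,
    seed: int = 0,
    probe_freq_hz: float = 3800.0,
) -> SampledSignal:
    """Spike-like multiunit waveform: band-limited background noise plus
    stereotyped biphasic spikes at Poisson times, a fraction of them
    phase-locked to a probe tone."""
    if fs_hz < 10000:
        raise ValueError("fs_hz must be at least 10 kHz")
    if rate_hz < 0 or not 0 <= tone_locked_fraction <= 1:
        raise ValueError("invalid rate or tone-locked fraction")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    sos = scipy.signal.butter(4, [750.0, 10000.0], btype="band", fs=fs_hz, output="sos")
    background = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    background /= max(np.std(background), 1e-30)

    # biphasic spike template ~1 ms long (derivative of a Gaussian)
    tt = np.arange(-0.5e-3, 0.5e-3, 1.0 / fs_hz)
    template = -tt * np.exp(-(tt**2) / (2 * (0.15e-3) ** 2))
    template /= np.max(np.abs(template))

    sig = background.copy()
    n_spikes = rng.poisson(rate_hz * duration_s)
    if n_spikes > 0:
        n_locked = rng.binomial(n_spikes, tone_locked_fraction)
        t_free = rng.uniform(0, duration_s, n_spikes - n_locked)
        # locked spikes sit at the preferred phase of the probe tone (+ jitter)
        cycles = rng.integers(0, max(int(duration_s * probe_freq_hz), 1), n_locked)
        t_lock = (cycles + 0.25) / probe_freq_hz + rng.normal(
            0.0, 0.05 / probe_freq_hz, n_locked
        )
        for ts in np.concatenate([t_free, t_lock]):
            i0 = int(round(ts * fs_hz))
            if 0 <= i0 < n - template.size:
                sig[i0 : i0 + template.size] += snr * template
    return SampledSignal(sig, fs_hz, cf_hz=probe_freq_hz,
                         meta={"rate_hz": rate_hz, "seed": seed})


def gen_dpoae_sweep(
    dp_level_db_spl: float,
    primaries_level_db_spl: float = 65.0,
    noise_db_spl: float = 0.0,
    n_presentations: int = 10,
    fs_hz: float = 50000.0,
    seed: int = 0,
) -> list[DPOAESweep]:
    """Synthesize swept two-tone presentations with an embedded 2f1-f2 tone.

    f2 sweeps 0.5 -> 10 kHz over 4 s inside a 4.05 s tone with 25 ms
    raised-cosine ramps; the distortion product rides at ``dp_level_db_spl``.
    Returns ``n_presentations`` sweeps with independent white noise.
    """
    rng = np.random.default_rng(seed)
    proto = DPOAESweep(waveform=np.zeros(1), fs_hz=fs_hz)
    duration = proto.t0_s + proto.sweep_duration_s + 0.025
    n = int(round(duration * fs_hz))
    t = np.arange(n) / fs_hz
    phi2 = proto.phi2_at(t)
    phi1 = phi2 / proto.ratio
    phid = 2.0 * phi1 - phi2

    def amp(level_db):
        return np.sqrt(2.0) * P_REF_PA * 10.0 ** (level_db / 20.0)

    clean = (
        amp(primaries_level_db_spl) * (np.sin(phi1) + np.sin(phi2))
        + amp(dp_level_db_spl) * np.sin(phid)
    )
    ramp_n = int(round(0.025 * fs_hz))
    env = np.ones(n)
    ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp_n) / ramp_n)
    env[:ramp_n] = ramp
    env[-ramp_n:] = ramp[::-1]
    clean = clean * env

    noise_rms = P_REF_PA * 10.0 ** (noise_db_spl / 20.0)
    sweeps = []
    for k in range(n_presentations):
        w = clean + noise_rms * rng.standard_normal(n)
        sweeps.append(
            DPOAESweep(
                waveform=w,
                fs_hz=fs_hz,
                level_db_spl=primaries_level_db_spl,
                presentation=k,
            )
        )
    return sweeps
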