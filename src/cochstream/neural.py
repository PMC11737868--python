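"""Neural-response and DPOAE signal analysis.

Implements the experimental analysis chain used around round-window drug
delivery: the Teager energy operator applied to multiunit recordings, driven
responses (tone-evoked minus spontaneous Teager energy), normalized response
curves versus time since drug application, 75%-of-baseline effect times, and
swept-tone DPOAE level estimation by windowed least squares with an even/odd
presentation noise floor and the 5 dB pre/post exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SampledSignal",
    "NeuralResponseSeries",
    "DPOAESweep",
    "UNREACHED",
    "teager_transform",
    "driven_response",
    "normalize_series",
    "effect_time",
    "average_presentations",
    "dpoae_level_track",
    "dpoae_noise_floor",
    "dpoae_change",
]

P_REF_PA = 20e-6
#: sentinel for curves that never cross the threshold
UNREACHED = float("nan")

CONDITIONS = ("silence", "sound", "post_SA", "LF_tone", "MF_tone")


@dataclass
class SampledSignal:
    """A uniformly sampled waveform with channel metadata."""

    samples: np.ndarray
    fs_hz: float
    cf_hz: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


@dataclass
class NeuralResponseSeries:
    """Driven-response amplitude versus time since drug application.

    ``t_min`` is minutes relative to application (negative = baseline window);
    ``response`` is the driven-response amplitude (arbitrary units) or, after
    :func:`normalize_series`, the dimensionless normalized response.
    """

    t_min: np.ndarray
    response: np.ndarray
    cf_hz: float
    condition: str
    animal_id: str | None = None
    normalized: bool = False

    def __post_init__(self):
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.t_min.shape != self.response.shape:
            raise ValueError("t_min and response must have the same shape")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("t_min must be strictly increasing")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


def teager_transform(sig: SampledSignal) -> SampledSignal:
    """Discrete Teager energy operator psi[n] = x[n]^2 - x[n-1]*x[n+1].

    Emphasizes spiking activity (instantaneous amplitude^2 * frequency^2 for
    slow sinusoids).  Output is two samples shorter than the input.
    """
    x = sig.samples
    if x.size < 3:
        raise ValueError("Teager transform needs at least 3 samples")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return SampledSignal(psi, sig.fs_hz, sig.cf_hz, dict(sig.meta))


def driven_response(tone_teager_mean: float, spontaneous_teager_mean: float,
                    with_flag: bool = False):
    """Driven response = tone-evoked minus spontaneous mean Teager energy.

    Floored at zero; ``with_flag=True`` also returns whether flooring occurred
    (spontaneous exceeding the evoked response).
    """
    if tone_teager_mean < 0 or spontaneous_teager_mean < 0:
        raise ValueError("mean Teager energies must be non-negative")
    d = tone_teager_mean - spontaneous_teager_mean
    floored = d < 0
    val = max(d, 0.0)
    return (val, floored) if with_flag else val


def normalize_series(series: NeuralResponseSeries, min_baseline: int = 3) -> NeuralResponseSeries:
    """Normalize by the mean driven response over the pre-application window
    (all samples with t < 0)."""
    pre = series.response[series.t_min < 0]
    if pre.size < min_baseline:
        raise ValueError(
            f"need >= {min_baseline} baseline samples (t < 0), got {pre.size}"
        )
    base = float(np.mean(pre))
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return replace(series, response=series.response / base, normalized=True)


def effect_time(
    series: NeuralResponseSeries,
    threshold: float = 0.75,
    sustain: int = 3,
) -> float:
    """Time [min] at which the normalized response drops below ``threshold``.

    The crossing must be sustained: the response stays below threshold for
    ``sustain`` consecutive samples (rejects noise dips; ``sustain=1``
    reproduces a naive first crossing).  The crossing instant interpolates
    linearly between the bracketing samples.  Returns NaN when the curve
    never crosses (excluded from downstream statistics).
    """
    s = series if series.normalized else normalize_series(series)
    r = s.response
    t = s.t_min
    below = r < threshold
    # first index where `sustain` consecutive samples are below
    run = 0
    start = None
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= sustain:
            start = i - sustain + 1
            break
    if start is None:
        return UNREACHED
    if start == 0:
        return float(t[0])
    # linear interpolation across the crossing
    r0, r1 = r[start - 1], r[start]
    f = (threshold - r0) / (r1 - r0)
    return float(t[start - 1] + f * (t[start] - t[start - 1]))


# ---------------------------------------------------------------------------
# DPOAE swept-tone analysis
# ---------------------------------------------------------------------------

@dataclass
class DPOAESweep:
    """One presentation of the swept two-tone stimulus response.

    f2 sweeps linearly from ``f2_start_hz`` to ``f2_end_hz`` over
    ``sweep_duration_s`` (starting at ``t0_s``); f1 = f2 / ``ratio`` with the
    standard ratio 1.25.  ``waveform`` is the microphone signal in Pa.
    """

    waveform: np.ndarray
    fs_hz: float
    f2_start_hz: float = 500.0
    f2_end_hz: float = 10000.0
    sweep_duration_s: float = 4.0
    t0_s: float = 0.025
    ratio: float = 1.25
    level_db_spl: float | None = None
    presentation: int = 0

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float)
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if self.ratio <= 1.0:
            raise ValueError("f2/f1 ratio must exceed 1")

    @property
    def sweep_rate(self) -> float:
        return (self.f2_end_hz - self.f2_start_hz) / self.sweep_duration_s

    def f2_at(self, t_s):
        tau = np.clip(np.asarray(t_s, dtype=float) - self.t0_s, 0.0, self.sweep_duration_s)
        return self.f2_start_hz + self.sweep_rate * tau

    def phi2_at(self, t_s):
        """Phase of the f2 primary (2*pi*integral of f2)."""
        t = np.asarray(t_s, dtype=float)
        tau = np.clip(t - self.t0_s, 0.0, self.sweep_duration_s)
        pre = np.minimum(t, self.t0_s) * self.f2_start_hz
        post = np.maximum(t - self.t0_s - self.sweep_duration_s, 0.0) * self.f2_end_hz
        return 2.0 * np.pi * (pre + self.f2_start_hz * tau
                              + 0.5 * self.sweep_rate * tau**2 + post)


def average_presentations(sweeps) -> DPOAESweep:
    """Average the waveforms of repeated presentations (signal path)."""
    sweeps = list(sweeps)
    if len(sweeps) < 1:
        raise ValueError("need at least one presentation")
    w = np.mean([s.waveform for s in sweeps], axis=0)
    return replace(sweeps[0], waveform=w)


def _track(sweep: DPOAESweep, window_s: float, step_s: float):
    """Windowed least-squares fit of the DP and primary components.

    Per Hann window: regress the waveform on sin/cos pairs at the
    instantaneous phases of f1, f2 and 2f1-f2 (plus a DC term), and convert
    the 2f1-f2 amplitude to dB SPL (rms re 20 uPa).
    """
    n = sweep.waveform.size
    fs = sweep.fs_hz
    nw = int(round(window_s * fs))
    if nw > n:
        raise ValueError("analysis window longer than the sweep")
    if nw < 8:
        raise ValueError("analysis window too short")
    step = max(int(round(step_s * fs)), 1)
    hann = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(nw) / (nw - 1))

    freqs, levels = [], []
    start = 0
    while start + nw <= n:
        idx = np.arange(start, start + nw)
        t = idx / fs
        tc = t[nw // 2]
        # skip windows not fully inside the swept interval
        if t[0] >= sweep.t0_s and t[-1] <= sweep.t0_s + sweep.sweep_duration_s:
            phi2 = sweep.phi2_at(t)
            phi1 = phi2 / sweep.ratio
            phid = 2.0 * phi1 - phi2
            X = np.column_stack([
                np.cos(phid), np.sin(phid),
                np.cos(phi1), np.sin(phi1),
                np.cos(phi2), np.sin(phi2),
                np.ones(nw),
            ])
            y = sweep.waveform[idx]
            Xw = X * hann[:, None]
            coef, *_ = np.linalg.lstsq(Xw, y * hann, rcond=None)
            amp = float(np.hypot(coef[0], coef[1]))
            rms = amp / np.sqrt(2.0)
            level = 20.0 * np.log10(max(rms / P_REF_PA, 1e-20))  # cap at -400 dB
            f2c = float(sweep.f2_at(tc))
            freqs.append(f2c * (2.0 / sweep.ratio - 1.0))  # 2 f1 - f2
            levels.append(level)
        start += step
    if not freqs:
        raise ValueError("no analysis window fits inside the swept interval")
    return np.asarray(freqs), np.asarray(levels)


def dpoae_level_track(sweep: DPOAESweep, window_s: float = 0.1, step_s: float = 0.02):
    """DP (2f1-f2) level track of an (averaged) sweep: (freq_hz, level_db_spl)."""
    return _track(sweep, window_s, step_s)


def dpoae_noise_floor(presentations, window_s: float = 0.1, step_s: float = 0.02):
    """Noise-floor track from the even/odd presentation difference.

    The 'null' waveform (mean of even-numbered presentations minus mean of
    odd-numbered ones, halved) cancels every deterministic component and is
    processed identically to the signal path.
    """
    presentations = list(presentations)
    if len(presentations) < 2:
        raise ValueError("noise floor needs at least 2 presentations")
    evens = [s.waveform for s in presentations[0::2]]
    odds = [s.waveform for s in presentations[1::2]]
    null = 0.5 * (np.mean(evens, axis=0) - np.mean(odds, axis=0))
    null_sweep = replace(presentations[0], waveform=null)
    return _track(null_sweep, window_s, step_s)


def dpoae_change(pre_track, post_track, band_hz=(100.0, 10000.0)):
    """Maximum |level difference| between pre and post tracks within the band.

    Returns ``(max_abs_change_db, excluded)`` where ``excluded`` is True when
    the change exceeds 5 dB at any frequency in the band (strictly more than
    5 dB; an exact 5 dB change is kept).
    """
    f_pre, l_pre = pre_track
    f_post, l_post = post_track
    if len(f_pre) != len(f_post) or not np.allclose(f_pre, f_post):
        raise ValueError("tracks must share a common frequency grid")
    m = (f_pre >= band_hz[0]) & (f_pre <= band_hz[1])
    if not np.any(m):
        raise ValueError("no track points inside the comparison band")
    diff = float(np.max(np.abs(np.asarray(l_post)[m] - np.asarray(l_pre)[m])))
    return diff, diff > 5.0
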