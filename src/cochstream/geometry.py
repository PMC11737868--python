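"""Reduced two-layer cochlear geometry, tonotopy, and the traveling-wave surrogate.

The cochlear fluid spaces are collapsed to a 2-D domain of length ``L`` (base at
``x = 0``, apex at ``x = L``): the scala tympani occupies ``0 <= y <= h_st`` and
the Corti duct (the fluid inside the organ of Corti) is stacked above it,
``h_st <= y <= h_st + h_c``, separated by the basilar membrane treated as a
zero-thickness permeable interface.  Sound enters as a basilar-membrane
traveling wave; outer-hair-cell (OHC) activity adds a differential motion of
the duct's top wall so the duct cross-section oscillates like a peristaltic
pump.  This module supplies the wall kinematics that drive the flow stage; the
upstream fluid–structure problem itself is replaced by a parametric surrogate.

Conventions
-----------
* All quantities SI.  ``x`` increases base -> apex, ``y`` upward.
* Bottom-wall (basilar-membrane) displacement:
  ``d_b(x, t) = A_b(x) * cos(omega * t - phi(x))``, with ``phi`` the
  accumulated phase lag (non-decreasing: the wave travels apically with
  decaying phase velocity ``omega / k(x)``).
* Top-wall displacement: ``d_t(x, t) = A_t(x) * cos(omega * t - phi(x) - psi(x))``
  (``psi > 0`` = top wall lags the membrane).  In passive mode
  (``ohc_active=False``) the two walls move identically, so the duct
  cross-sectional area never changes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "GERBIL_MAP_PARAMS",
    "CochlearGeometry",
    "Stimulus",
    "WaveParams",
    "TravelingWaveField",
    "build_geometry",
    "geometry_to_yaml",
    "cf_from_place",
    "place_from_cf",
    "synthesize_wave",
    "wall_kinematics",
]

P_REF_PA = 20e-6  # 0 dB SPL reference pressure

#: Greenwood-form map constants for the ~12 mm gerbil cochlea,
#: CF(x) = A * (10 ** (a * (1 - x / L)) - k)  [Hz].
#: Close to the published gerbil fit (apex ~0.05 kHz, base ~44 kHz).
GERBIL_MAP_PARAMS = {"A_hz": 350.0, "a": 2.1, "k": 0.85}


@dataclass(frozen=True)
class CochlearGeometry:
    """Two-layer rectangular fluid domain plus place-frequency map.

    The flow solver requires a single uniform vertical cell size, so
    ``h_corti / ny_corti`` must equal ``h_scala / ny_scala``.
    """

    length_m: float = 12e-3
    h_corti_m: float = 80e-6
    h_scala_m: float = 500e-6
    membrane_thickness_m: float = 0.0
    map_params: dict = field(default_factory=lambda: dict(GERBIL_MAP_PARAMS))
    nx: int = 360
    ny_corti: int = 8
    ny_scala: int = 50

    def __post_init__(self):
        for name in ("length_m", "h_corti_m", "h_scala_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.membrane_thickness_m < 0:
            raise ValueError("membrane_thickness_m must be non-negative")
        for name in ("nx", "ny_corti", "ny_scala"):
            if int(getattr(self, name)) < 2:
                raise ValueError(f"{name} must be an integer >= 2")
        dy_c = self.h_corti_m / self.ny_corti
        dy_s = self.h_scala_m / self.ny_scala
        if abs(dy_c - dy_s) > 1e-9 * max(dy_c, dy_s):
            raise ValueError(
                "grid must have one uniform dy: h_corti_m/ny_corti must equal "
                f"h_scala_m/ny_scala (got {dy_c:.3e} vs {dy_s:.3e})"
            )
        for key in ("A_hz", "a", "k"):
            if key not in self.map_params:
                raise ValueError(f"map_params missing constant {key!r}")

    # -- derived grid coordinates -------------------------------------------------
    @property
    def dx(self) -> float:
        return self.length_m / self.nx

    @property
    def dy(self) -> float:
        return self.h_corti_m / self.ny_corti

    @property
    def ny(self) -> int:
        return self.ny_corti + self.ny_scala

    @property
    def x_faces(self) -> np.ndarray:
        return np.linspace(0.0, self.length_m, self.nx + 1)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_faces[1:] + self.x_faces[:-1])

    @property
    def y_faces(self) -> np.ndarray:
        return np.linspace(0.0, self.h_scala_m + self.h_corti_m, self.ny + 1)

    @property
    def y_centers(self) -> np.ndarray:
        yf = self.y_faces
        return 0.5 * (yf[1:] + yf[:-1])

    @property
    def membrane_index(self) -> int:
        """Index of the y-face carrying the basilar membrane."""
        return self.ny_scala

    def cf_range_hz(self) -> tuple[float, float]:
        """(lowest, highest) characteristic frequency covered by the map."""
        return (cf_from_place(self, self.length_m), cf_from_place(self, 0.0))

    def stokes_layer_cells(self, nu_m2_s: float, frequency_hz: float) -> float:
        """Number of cells across the Stokes layer delta = sqrt(nu/omega)."""
        delta = np.sqrt(nu_m2_s / (2.0 * np.pi * frequency_hz))
        return delta / self.dy

    def to_dict(self) -> dict:
        d = asdict(self)
        d["map_params"] = dict(self.map_params)
        return d


@dataclass(frozen=True)
class Stimulus:
    """Acoustic stimulus: a tone, a broadband band, or silence.

    ``level_db_spl`` is re 20 µPa.  Broadband stimuli are handled by callers as
    a finite sum of tones; this type only carries the band edges.
    """

    kind: str = "tone"
    frequency_hz: float | None = 1000.0
    band_hz: tuple[float, float] | None = None
    level_db_spl: float = 80.0

    def __post_init__(self):
        if self.kind not in ("tone", "broadband", "silence"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not np.isfinite(self.level_db_spl):
            raise ValueError("level_db_spl must be finite")
        if self.kind == "tone" and (self.frequency_hz is None or self.frequency_hz <= 0):
            raise ValueError("tone stimulus requires a positive frequency_hz")
        if self.kind == "broadband" and self.band_hz is None:
            raise ValueError("broadband stimulus requires band_hz")

    @property
    def pressure_pa(self) -> float:
        """Peak-equivalent pressure amplitude (0 for silence)."""
        if self.kind == "silence":
            return 0.0
        return P_REF_PA * 10.0 ** (self.level_db_spl / 20.0)


# ---------------------------------------------------------------------------
# place-frequency map (Greenwood form)
# ---------------------------------------------------------------------------

def cf_from_place(geom: CochlearGeometry, x_m) -> np.ndarray | float:
    """Characteristic frequency [Hz] at place ``x_m`` metres from the base."""
    x = np.asarray(x_m, dtype=float)
    if np.any(x < -1e-12) or np.any(x > geom.length_m + 1e-12):
        raise ValueError(f"place {x_m!r} outside [0, {geom.length_m}] m")
    p = geom.map_params
    cf = p["A_hz"] * (10.0 ** (p["a"] * (1.0 - x / geom.length_m)) - p["k"])
    return float(cf) if np.isscalar(x_m) else cf


def place_from_cf(geom: CochlearGeometry, f_hz) -> np.ndarray | float:
    """Place [m from base] of characteristic frequency ``f_hz`` (map inverse)."""
    f = np.asarray(f_hz, dtype=float)
    lo, hi = geom.cf_range_hz()
    if np.any(f < lo * (1 - 1e-12)) or np.any(f > hi * (1 + 1e-12)):
        raise ValueError(f"frequency {f_hz!r} Hz outside map range [{lo:.1f}, {hi:.1f}]")
    p = geom.map_params
    x = geom.length_m * (1.0 - np.log10(f / p["A_hz"] + p["k"]) / p["a"])
    x = np.clip(x, 0.0, geom.length_m)
    return float(x) if np.isscalar(f_hz) else x


# ---------------------------------------------------------------------------
# traveling-wave surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveParams:
    """Free parameters of the parametric traveling-wave surrogate.

    gain_m_per_pa
        Peak basilar-membrane displacement per unit ear-canal pressure.  The
        model is linear in pressure (no compressive nonlinearity), so this one
        constant sets the absolute scale of every downstream velocity; the
        default places an 80 dB SPL tone at ~2 µm peak displacement, which
        puts peak streaming at a few tenths of mm/s.
    rise_exponent
        Shape of the basal rise of the envelope ``(x/x_peak)^q * exp(q(1-x/x_peak))``.
    cutoff_len_m
        Gaussian roll-off length apical of the peak (sharp cutoff).
    k_base_rad_m, k_peak_rad_m, k_exponent
        Local wavenumber law ``k(x) = k_base + (k_peak-k_base)*(x/x_peak)^r``,
        held at ``k_peak`` apical of the peak; phase velocity omega/k therefore
        decays toward the apex.
    area_gain, area_phase_lag_rad
        OHC "area motor": in active mode the top wall acquires an extra
        component ``area_gain * A_b`` lagging the membrane by
        ``area_phase_lag_rad``, confined to the sub-peak tail.
    tail_len_m
        Length of the raised-cosine window (ending at ``x_peak``) on which the
        area motor acts.
    """

    gain_m_per_pa: float = 1.0e-5
    rise_exponent: float = 2.0
    cutoff_len_m: float = 0.6e-3
    k_base_rad_m: float = 800.0
    k_peak_rad_m: float = 8000.0
    k_exponent: float = 2.0
    area_gain: float = 2.0
    area_phase_lag_rad: float = -np.pi / 2
    tail_len_m: float = 3.0e-3


@dataclass(frozen=True)
class TravelingWaveField:
    """Per-place wall-motion amplitudes/phases at one stimulus frequency."""

    omega: float
    x_m: np.ndarray
    amp_bottom_m: np.ndarray
    phase_rad: np.ndarray
    amp_top_m: np.ndarray
    phase_offset_rad: np.ndarray
    ohc_active: bool
    x_peak_m: float

    def __post_init__(self):
        if np.any(self.amp_bottom_m < 0) or np.any(self.amp_top_m < 0):
            raise ValueError("wall amplitudes must be non-negative")
        if np.any(np.diff(self.phase_rad) < -1e-12):
            raise ValueError("phase lag must be non-decreasing toward the apex")

    @property
    def period_s(self) -> float:
        return 2.0 * np.pi / self.omega

    def complex_amplitude(self, surface: str, x_m) -> np.ndarray:
        """Complex displacement amplitude D(x); displacement = Re[D e^{-i omega t}]."""
        x = np.atleast_1d(np.asarray(x_m, dtype=float))
        if surface == "bottom":
            amp = np.interp(x, self.x_m, self.amp_bottom_m)
            ph = np.interp(x, self.x_m, self.phase_rad)
        elif surface == "top":
            amp = np.interp(x, self.x_m, self.amp_top_m)
            ph = np.interp(x, self.x_m, self.phase_rad + self.phase_offset_rad)
        else:
            raise ValueError(f"unknown surface {surface!r}; expected 'top' or 'bottom'")
        return amp * np.exp(1j * ph)


def _envelope(x: np.ndarray, x_peak: float, p: WaveParams) -> np.ndarray:
    s = x / x_peak
    env = s**p.rise_exponent * np.exp(p.rise_exponent * (1.0 - s))
    apical = x > x_peak
    env = np.where(apical, env * np.exp(-(((x - x_peak) / p.cutoff_len_m) ** 2)), env)
    return env


def _phase_lag(x: np.ndarray, x_peak: float, p: WaveParams) -> np.ndarray:
    """Integral of the wavenumber law (closed form)."""
    r = p.k_exponent
    dk = p.k_peak_rad_m - p.k_base_rad_m
    xs = np.minimum(x, x_peak)
    phi = p.k_base_rad_m * xs + dk * x_peak / (r + 1.0) * (xs / x_peak) ** (r + 1.0)
    beyond = np.maximum(x - x_peak, 0.0)
    return phi + p.k_peak_rad_m * beyond


def synthesize_wave(
    geom: CochlearGeometry,
    stim: Stimulus,
    ohc_active: bool = True,
    params: WaveParams | None = None,
    x_m: np.ndarray | None = None,
) -> TravelingWaveField:
    """Build the surrogate traveling wave for a tone stimulus.

    The envelope rises smoothly to the tonotopic place of the tone and cuts
    off sharply apical of it; amplitude is linear in stimulus pressure.  With
    ``ohc_active=False`` the top wall copies the membrane exactly (zero
    cross-sectional area change, the salicylate condition).
    """
    if params is None:
        params = WaveParams()
    if stim.kind == "broadband":
        raise ValueError("broadband stimuli must be decomposed into tones by the caller")
    if stim.kind == "tone":
        x_peak = place_from_cf(geom, stim.frequency_hz)  # raises if outside map
        omega = 2.0 * np.pi * stim.frequency_hz
    else:  # silence: keep a well-defined (zero-amplitude) field at 1 kHz
        x_peak = place_from_cf(geom, 1000.0)
        omega = 2.0 * np.pi * 1000.0

    x = geom.x_faces if x_m is None else np.asarray(x_m, dtype=float)
    amp_b = stim.pressure_pa * params.gain_m_per_pa * _envelope(x, x_peak, params)
    phi = _phase_lag(x, x_peak, params)

    if ohc_active:
        x0 = x_peak - params.tail_len_m
        w = np.where(
            (x >= x0) & (x <= x_peak),
            np.sin(np.pi * np.clip((x - x0) / params.tail_len_m, 0.0, 1.0)) ** 2,
            0.0,
        )
        top = 1.0 + params.area_gain * w * np.exp(1j * params.area_phase_lag_rad)
        amp_t = amp_b * np.abs(top)
        psi = np.angle(top)
    else:
        amp_t = amp_b.copy()
        psi = np.zeros_like(x)

    return TravelingWaveField(
        omega=omega,
        x_m=x,
        amp_bottom_m=amp_b,
        phase_rad=phi,
        amp_top_m=amp_t,
        phase_offset_rad=psi,
        ohc_active=bool(ohc_active),
        x_peak_m=float(x_peak),
    )


def wall_kinematics(wave: TravelingWaveField, surface: str, x_m, t_s):
    """Displacement [m] and its exact time derivative [m/s] of one wall.

    ``surface`` is ``'top'`` or ``'bottom'``; both outputs broadcast over
    ``x_m`` and ``t_s``.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_s must be non-negative")
    D = wave.complex_amplitude(surface, x_m)  # validates surface label
    phase = np.multiply.outer(t, np.ones_like(D, dtype=float)) * wave.omega
    disp = np.real(D * np.exp(-1j * phase))
    vel = np.real(-1j * wave.omega * D * np.exp(-1j * phase))
    if np.isscalar(t_s) and np.isscalar(x_m):
        return float(disp.ravel()[0]), float(vel.ravel()[0])
    return np.squeeze(disp), np.squeeze(vel)


# ---------------------------------------------------------------------------
# config plumbing
# ---------------------------------------------------------------------------

def build_geometry(config) -> CochlearGeometry:
    """Build a :class:`CochlearGeometry` from a YAML string/path/stream or dict.

    The config may be flat or carry a ``geometry:`` section; keys mirror the
    dataclass fields (SI units, unit suffixes in the names).
    """
    if isinstance(config, CochlearGeometry):
        return config
    if isinstance(config, dict):
        data = config
    else:
        if isinstance(config, (str, Path)) and "\n" not in str(config) and Path(config).exists():
            text = Path(config).read_text()
        elif isinstance(config, _io.IOBase):
            text = config.read()
        else:
            text = str(config)
        data = yaml.safe_load(text) or {}
    if "geometry" in data:
        data = data["geometry"]
    known = CochlearGeometry.__dataclass_fields__.keys()
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown geometry config keys: {sorted(unknown)}")
    return CochlearGeometry(**data)


def geometry_to_yaml(geom: CochlearGeometry) -> str:
    """Serialize a geometry back to YAML (round-trips through build_geometry)."""
    return yaml.safe_dump({"geometry": geom.to_dict()}, sort_keys=True)
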