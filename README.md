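# cochstream

Modelling and analysis tools for **sound-driven cochlear fluid streaming and
inner-ear drug transport**.

Drugs applied at the round window reach apical (low-frequency) cochlear
locations only slowly by diffusion along the scala tympani. Sound can speed
this up: outer hair cells (OHCs), driven by the basilar-membrane traveling
wave, oscillate the cross-section of the organ-of-Corti fluid duct, which acts
as a peristaltic micro-pump. The period-averaged (steady-streaming) flow runs
apically along the Corti duct and returns basally along the scala tympani, and
this circulation advects drug far faster than diffusion alone in the
traveling-wave tail. `cochstream` implements the full modelling chain for this
mechanism, together with the signal-analysis and cohort-statistics chain used
to quantify it experimentally, exercisable entirely on synthetic inputs. It is
aimed at auditory biophysicists and modellers of inner-ear pharmacokinetics.

## The model

The cochlear fluid spaces are reduced to a 2-D two-layer domain (12 mm long):
the Corti duct stacked on the scala tympani, separated by the basilar
membrane (BM), with a Greenwood-form place–frequency map (gerbil constants by
default). A parametric traveling-wave surrogate supplies the wall kinematics:
bottom-wall (BM) displacement `A_b(x) cos(ωt − φ(x))` peaking at the
tonotopic place of the stimulus, with phase velocity `ω/k(x)` decaying toward
the apex, and — in the active (OHC-on) state — a differential top-wall
component confined to the sub-peak tail that makes the duct area oscillate.

1. **Oscillatory flow.** Incompressible Navier–Stokes with the advection term
   retained (it is the streaming source),

       ∂u/∂t + (u·∇)u = −(1/ρ)∇p + ν∇²u,   ∇·u = 0,

   with ν = 70×10⁻⁶ m²/s (one hundred times water, the effective value for
   the finely subdivided Corti fluid) and ρ = 1000 kg/m³. The BM is a
   zero-thickness Darcy interface: the transmembrane exchange velocity is
   `u_p = −K Δp` with `Δp = p_corti − p_scala` and `K = 1 m/(s·Pa)`, and the
   fluid velocity at the membrane is `u_f = u_m + u_p`. Discretization is a
   staggered-grid Crank–Nicolson projection scheme; wall motion is
   transferred to the fixed mean boundary including the second-order slip
   `u = −η ∂u/∂y` that carries no-slip from the displaced wall (the
   peristaltic transport term). Integration runs from rest to a periodic
   steady state (5 ms suffices at 1 kHz).

2. **Drift.** The steady streaming field is the Eulerian mean over one
   period at fixed positions, `u_D(x) = (1/T)∫ u dt`; a particle tracker
   provides the Lagrangian cross-check.

3. **Transport.** Drug concentration obeys `∂C/∂t = D∇²C − u_D·∇C` with a
   constant 10 mM source on the round-window patch, zero-flux walls, and a
   solute-permeable BM. Finite volumes with Scharfetter–Gummel exponential
   fluxes and adaptive implicit stepping (initial step = one stimulus
   period) keep the scheme conservative and bounds-preserving. The **effect
   time** at a place is the first time its concentration reaches 1% of the
   source (100 µM), read out at Corti-duct mid-height.

4. **Measurement analysis.** Teager energy operator
   `ψ[n] = x[n]² − x[n−1]x[n+1]` for multiunit responses; driven response =
   tone-evoked minus spontaneous Teager mean; experimental effect time = the
   sustained 75%-of-baseline crossing of the normalized response; swept-tone
   DPOAE level at 2f₁−f₂ (f₂ = 1.25 f₁, 0.5→10 kHz in 4 s) by least squares
   in 100 ms Hann windows stepped by 20 ms, with an even/odd presentation
   noise floor and a >5 dB pre/post change exclusion rule.

5. **Cohort statistics.** The silence-case records fix the diffusion trend
   `t_Trend(x) = x²/(4 D_eff z²)`, `z = erfc⁻¹(0.01)`, fitted in log-time;
   effect times are normalized as `t_E[dB] = 20 log₁₀(t_E/t_Trend)` and
   compared between conditions with Welch two-tailed t-tests, overall and
   split at 4.5 kHz.

A synthetic-data module generates response curves, cohorts, spike-like
waveforms and DPOAE sweeps with known ground truth, so every stage is
testable without any external data.

## Worked example

Simulate delivery under a continuous 1 kHz, 80 dB SPL tone and compare with
silence:

```python
import numpy as np
from cochstream import *

geom = CochlearGeometry()                        # 12 mm two-layer domain
stim = Stimulus(kind="tone", frequency_hz=1000.0, level_db_spl=80.0)
wave = synthesize_wave(geom, stim, ohc_active=True)

drift = compute_drift(solve_oscillatory_flow(geom, wave))
print(f"peak streaming speed: {drift.peak_speed()*1e3:.2f} mm/s")

outs = np.geomspace(1.0, 1.2e4, 70)
silence = solve_transport(geom, None, 1e-9, TransportBC(), 1.2e4, outs)
sound = solve_transport(geom, drift, 1e-9, TransportBC(), 1.2e4, outs)
te_sil = effect_time_map(silence)
te_snd = effect_time_map(sound)

i = np.argmin(np.abs(te_sil.x_m - place_from_cf(geom, 6000.0)))
print(f"effect time at the 6 kHz place: silence {te_sil.te_s[i]/60:.1f} min, "
      f"sound {te_snd.te_s[i]/60:.1f} min")
```

prints

```
peak streaming speed: 0.26 mm/s
effect time at the 6 kHz place: silence 31.4 min, sound 16.0 min
```

— the sound-driven circulation nearly halves the time for the drug to reach
the 6 kHz place (a −5.8 dB facilitation), and the facilitation collapses at a
stalling point just apical of the traveling-wave peak where the streaming
cell closes.

The statistics chain, on a synthetic cohort mirroring the measured design
(48 silence / 34 sound records, −6 dB facilitation at high CF, 3 dB scatter):

```python
coh = gen_cohort(CohortSpec(seed=1))
silence, sound = (coh[coh.condition == c] for c in ("silence", "sound"))
trend = fit_diffusion_trend(silence)
print(trend.summary())
print(compare_groups(silence, sound, trend).summary())
```

```
Effect-time diffusion trend (log-space least squares)
--------------------------------------------------------
records (n)          : 48
threshold fraction   : 0.01
D_eff [m^2/s]        : 1.008e-09 (95% CI 9.345e-10 .. 1.088e-09)
exponent of tE ~ x^b : 2.000  [fixed]
residual SD [dB]     : 2.33

Effect-time comparison (Welch two-tailed t; CF split 4.5 kHz)
------------------------------------------------------------------------
stratum     n_a  n_b   mean_a   mean_b       t          p
whole        48   34    -0.00    -3.09    4.31   7.44e-05
low_cf       21   20     0.04    -0.75    1.08      0.289
high_cf      27   14    -0.03    -6.43    7.90   3.64e-08
```

The generated −6 dB high-CF facilitation is recovered (high-CF stratum highly
significant, low-CF not), and the fitted effective diffusion constant matches
the generator's 1.0×10⁻⁹ m²/s within its confidence interval.

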