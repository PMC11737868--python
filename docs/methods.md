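# Methods

This note documents the models, the defaults and the numerical choices behind
`cochstream`, and what the synthetic benchmarks do and do not establish.

## Domain and tonotopy

The cochlear fluid spaces are collapsed to a 2-D slab after removing the
radial dimension: the scala tympani (default height 500 µm, 50 cells) below
and the Corti duct (80 µm, 8 cells) above, length 12 mm (gerbil scale), both
with a single uniform vertical cell size (a solver requirement). The basilar
membrane (BM) is a zero-thickness interface at the shared face. Scala media
and scala vestibuli are omitted; the apical and basal ends are rigid no-slip
walls (no helicotrema — a known limitation, see below).

The place–frequency map is Greenwood-form, `CF(x) = A(10^{a(1−x/L)} − k)` with
gerbil-like constants A = 350 Hz, a = 2.1, k = 0.85 (≈52 Hz at the apex,
≈44 kHz at the base; the 1 kHz place falls at 8.75 mm). The constants are
configuration parameters, so any species' map can be substituted.

## Traveling-wave surrogate

The upstream fluid–structure problem (scala pressure ↔ organ-of-Corti
micromechanics with OHC feedback) is replaced by a parametric surrogate with
the features that matter for pumping:

* **Envelope** `(x/x_p)^q e^{q(1−x/x_p)}` (q = 2) rising to the tonotopic
  place `x_p`, with a Gaussian apical cutoff (roll-off length 0.6 mm).
* **Phase** `φ(x) = ∫k dx` with `k(x)` growing from 800 to 8000 rad/m toward
  the peak, so the phase velocity decays apically (≈0.8 m/s at the peak for
  1 kHz).
* **Level scaling** strictly linear in ear-canal pressure (the model has no
  compressive nonlinearity); the gain default 1.0×10⁻⁵ m/Pa puts an
  80 dB SPL tone at 2 µm peak BM displacement.
* **OHC area motor**: in the active state the top wall acquires an extra
  component `g·A_b` with a 90° phase lead, windowed (raised cosine) over the
  3 mm tail ending at the peak; defaults g = 2, lead = π/2. In the passive
  (salicylate) state the two walls move identically — the duct area never
  changes.

The surrogate's absolute amplitudes are the one genuinely uncalibrated input:
no stage-1 deformation amplitudes are available to pin them. The defaults
were chosen once so that (i) displacements stay well below the duct height
and below the wall-adjacent grid cell (a validity requirement of the
linearized wall transfer), and (ii) the peak streaming lands at a few tenths
of mm/s. Millimetre-per-second streaming of the kind a full deforming-mesh
stage-1/stage-2 chain can produce would need amplitudes outside the
linearized transfer's validity domain here, so magnitudes should be read as
order-of-magnitude; directions, scalings and all downstream statistics are
insensitive to this calibration.

Broadband stimuli are represented as finite sums of tones solved per
component; superposing their drifts neglects cross-frequency Reynolds
stresses and is flagged as an approximation.

## Oscillatory flow

Incompressible Navier–Stokes with the advection term retained, ν = 70×10⁻⁶
m²/s (100× water — the effective viscosity of the finely subdivided Corti
fluid spaces; one value for both layers by default, per-layer override
available), ρ = 1000 kg/m³.

* **Discretization**: staggered (MAC) finite differences, uniform grid;
  Crank–Nicolson viscous terms, Adams–Bashforth-extrapolated advection,
  incremental pressure projection with a direct sparse factorization.
* **Membrane**: Darcy exchange `u_p = −K(p_corti − p_scala)`, K = 1 m/(s·Pa).
  The exchange enters the pressure Poisson equation implicitly (a membrane
  face conductance replacing the usual `Δt/(ρΔy)`), which keeps this very
  permeable membrane unconditionally stable; tangentially the membrane is a
  no-slip wall for both layers. Drift is insensitive to K over at least
  0.3–3 m/(s·Pa) (validated in the acceptance suite).
* **Wall transfer**: wall motion is imposed at the fixed mean boundary
  (displacement ≪ layer height; no ALE). The no-slip condition is carried
  from the displaced wall to the mean line at second order, giving the
  tangential slip `u = −η ∂u/∂y`; the corresponding normal correction
  vanishes at that order for walls that move only normally. This slip is
  essential physics: without it a fixed-mesh solver has no peristaltic mass
  transport at all and the duct cannot pump. The wall gradient feeding the
  slip is estimated one-sidedly from the three interior cells and smoothed
  by a per-step exponential moving average (weight 0.5) to damp a weak
  numerical feedback loop; the benchmark cost of the filter is a few percent
  of the slip amplitude. Validity requires η < Δy/2 (enforced).
* **Closed-box compatibility**: rigid ends force the prescribed outer-wall
  normal flux to integrate to zero at every instant; the top-wall complex
  amplitude is projected onto zero mean (a uniform correction, small when
  several wavelengths fit in the duct).
* **Resolution rules**: the grid must put ≥8 cells across the Stokes layer
  `δ = (ν/ω)^{1/2}` (105 µm at 1 kHz with this ν — the whole Corti duct is
  boundary layer, Womersley number ≈0.8); the time step defaults to T/100
  (10 µs at 1 kHz, scaled with 1/f).
* **Periodic steady state**: integration starts from rest and stops when the
  relative L2 change between consecutive periods falls below 1e-4; with
  these parameters the viscous transient dies within a fraction of a period
  and 3–5 periods (≈5 ms at 1 kHz) suffice. Non-convergence raises with the
  residual history attached.
* **Drift**: the Eulerian mean of the stored final period at fixed points
  (uniform sampling makes the quadrature spectrally accurate). This is what
  feeds transport; the Lagrangian (tracer) mean additionally contains Stokes
  drift, and the particle tracker exists to quantify that difference — only
  sign agreement at seed points is asserted, not magnitude.

### Flow benchmarks

* **Stokes layer**: a tangentially oscillating wall reproduces
  `U0 e^{−y/δ'} cos(ωt − y/δ')`, `δ' = (2ν/ω)^{1/2}`, to 3.5×10⁻⁴ relative
  RMS (tolerance 1e-3).
* **Small-amplitude peristalsis**: a waving-wall channel at ε = 0.004 matches
  an independently implemented second-order long-wave expansion (closed-form
  first-order oscillatory flow at arbitrary Womersley number, Reynolds-stress
  forced steady second order, plus the same wall slip) within 2–4% (tolerance
  10%), both with and without the slip term. The benchmark runs at a strong
  Womersley number (ν = 2×10⁻⁶ m²/s, h = 100 µm, 1 kHz): in the
  viscous-dominated regime the mean force is a ~1% cancellation residual of
  the leading long-wave terms and no 10% comparison would be meaningful.
* **Null control**: with zero area change and both quadratic terms (advection
  and wall slip) disabled, the problem is linear and the residual drift is
  ~1e-13 of the oscillatory speed (tolerance 1%).

## Solute transport

`∂C/∂t = D∇²C − u_D·∇C` with C fixed at 10 mM on the source patch (default:
the basal-most 0.2 mm of the scala floor, standing in for the round-window
niche; configurable, including a whole-basal-face mode that makes the problem
exactly 1-D for validation), zero flux elsewhere. D defaults to 1.0×10⁻⁹ m²/s
(small-molecule order; the paper-style phenomenology is D-agnostic). The BM
passes solute by the mean Darcy exchange flow plus diffusive contact
(scale factor configurable down to an advectively-coupled-only membrane).

Finite volumes with Scharfetter–Gummel exponential face fluxes: monotone at
any cell Péclet number (the drift field reaches cell Péclet ≈ 10 at the
default desk-scale mesh), second-order at small Péclet, and exactly
conservative — the interior mass gain matches the discrete source influx to
~0.1% per output interval (tolerance 0.5%). A central-difference scheme is
available and refuses Péclet-violating meshes with a diagnostic. Time
stepping starts at one stimulus period (1 ms at 1 kHz) and grows
geometrically (factor 1.08); variable-step BDF2 after a 3-step
backward-Euler start gives second-order accuracy (pure backward Euler is
available where strict positivity matters, e.g. advected pulses). The
1-D diffusion benchmark matches `C0·erfc(x/(2√(Dt)))` to 0.4% max relative
error over the concentration range that defines effect times (tolerance 2%).

**Effect time** = first crossing of 1% of the source concentration (100 µM),
read out at Corti-duct mid-height (the drug must reach the inner hair cells;
a scala-top readout is available), interpolated linearly between stored
outputs; non-monotone histories are flagged and never-crossing places
returned as NaN. The closed-form inversion of the 1-D profile,
`t_E = x²/(4Dz²)` with `z = erfc⁻¹(0.01)`, is recovered to 0.4%.

With the active-wave drift the facilitation ratio `t_E(sound)/t_E(silence)`
falls to ≈0.25 through the traveling-wave tail and collapses back toward 1
at a stalling point just apical of the wave peak, where the streaming cell
closes — the fast track ends there and diffusion takes over.

## Measurement-analysis chain

* **Teager operator** `ψ[n] = x[n]² − x[n−1]x[n+1]` (length n−2); on a
  sinusoid it is the constant `A² sin²Ω` (machine-precision validated).
* **Driven response**: tone-evoked minus spontaneous mean Teager energy,
  floored at zero with a flag.
* **Normalization**: baseline = mean driven response over all pre-application
  samples (t < 0, at least 3) — the baseline window is otherwise
  unconstrained by the protocol description, so this is the package's
  convention.
* **Effect time**: first sustained crossing below 75% of baseline
  (3 consecutive samples by default — bimodal decays make a single-sample
  rule fragile; 1 reproduces the naive rule), linearly interpolated.
  Curves that never cross return NaN and are excluded listwise downstream
  (with a logged count).
* **DPOAE**: least-squares fit of sin/cos pairs at the exact chirp phases of
  f1, f2 and 2f1−f2 (plus DC) in 100 ms Hann-weighted windows stepped by
  20 ms; levels in dB SPL re 20 µPa (rms). The noise floor processes the
  half-difference of even- and odd-presentation averages identically, which
  cancels every deterministic component (capped at −400 dB); the estimator
  recovers embedded components within ~0.2 dB at ≥10 dB SNR (tolerance
  1 dB). Pre/post tracks differing by more than 5 dB anywhere in
  0.1–10 kHz flag the measurement for exclusion (exactly 5 dB is kept).

## Cohort statistics

`DiffusionTrend` fits `t_E = x²/(4 D_eff z²)` to the silence records by least
squares in log10-time — errors are treated as multiplicative, consistent with
the dB presentation of residuals; whether to fit in linear or log time is
otherwise an open choice and log is this package's default. A free-exponent
variant (`tE ~ x^b`) serves as a diagnostic of the square law. Effect times
are normalized as `t_E[dB] = 20 log10(t_E/t_Trend)` (scale-free by
construction) and compared with Welch two-tailed t-tests — the protocol
specifies only "t-tests", and unequal variances across conditions are the
safer default — overall and split at 4.5 kHz (a boundary CF goes to the low
stratum). Strata with fewer than two records per group are marked not
computable rather than failing the whole comparison.

## Synthetic data

The generators emulate the measured data's structure with known ground truth:

* **Response curves**: logistic decay from a unity baseline with the
  noiseless 75% crossing placed exactly at the requested effect time,
  optional bimodal plateau, multiplicative Gaussian noise, sampled on the
  57.2 s stimulus-sequence grid (51 pips + pause).
* **Cohorts**: default 48 silence / 34 sound records (the measured design),
  CF log-uniform over 1–20 kHz, effect times = trend × condition offset ×
  lognormal noise (σ = 3 dB — matching the residual scatter the trend fit
  recovers). Condition offsets default to the qualitative measured pattern
  (sound and mid-frequency tone: −6 dB above 4.5 kHz only; low-frequency
  tone: −8/−5 dB everywhere; salicylate pre-treatment: none); the magnitudes
  are free parameters of the generator, not measured values.
* **Spike signals**: 0.75–10 kHz band-limited background plus biphasic
  ~1 ms spikes at Poisson times, optionally phase-locked to a probe tone.
* **DPOAE sweeps**: the full stimulus protocol (4.05 s, 25 ms raised-cosine
  ramps, f2 = 1.25 f1 from 0.5 to 10 kHz over 4 s, 10 presentations) with an
  embedded 2f1−f2 component of known level and independent white noise.

All generators are bit-reproducible under a fixed seed, and with noise
switched off they satisfy the downstream analysis model exactly. What passing
tests show is therefore internal consistency (estimators recover their own
generative model, solvers match independent closed forms) — not that real
AVCN recordings or real cochleae obey these models: the generators contain no
adaptation, no anesthesia drift, no electrode artifacts, and the flow model
contains no 3-D geometry, no compressive nonlinearity, no feedback from the
flow onto the wave.

## Known limitations

* One-way coupling only (wave → flow → transport); no fluid–structure
  feedback, no compressibility, no 3-D effects.
* Closed rigid ends: the helicotrema and round/oval-window compliance are
  not modelled; the top-wall amplitude is projected onto zero net flux
  instead.
* Linearized wall transfer bounds usable wall amplitudes (η < Δy/2), which
  caps the absolute streaming magnitude the model can represent.
* Eulerian-mean drift drives transport; Stokes drift is quantified by the
  tracer but not added.
* No solute binding, clearance or uptake; no scala media/vestibuli; no
  electrochemical (K⁺) homeostasis.
* Statistics use plain Welch t-tests; repeated measures per animal are not
  modelled with mixed effects.

## Problem sizes used in the shipped tests

Flow: 360×58 cells (33 µm × 10 µm) for the full duct, 100 steps/period,
3–5 periods; benchmarks 128–256 cells per direction. Transport: the same
grid, ~170 adaptive steps to 1.2×10⁴ s, 70 stored snapshots. Statistics:
1000 null cohorts for the type-I check, 500 replicates for power, 25 for the
exponent ensemble. The full test suite runs in about two minutes on one CPU.
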