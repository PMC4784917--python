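# Methods

## Model

`msbsim` simulates the rotational dynamics of single-domain magnetic
nanoparticles whose moment is locked to the particle body, suspended in a
Newtonian fluid and driven by a uniaxial oscillating field
B(t) = B₀ cos(2πft) ẑ. Angular inertia is dropped (rotational Reynolds
number ρfd²/η ≈ 10⁻⁵ for water, kHz drives and 100 nm particles), leaving a
first-order stochastic equation for the unit magnetization vector **m**. In
dimensionless time t\* = tf:

dm = (ξ₀/2Ω) m × (cos 2πt\* ẑ × m) dt\* + m × dW/√Ω,

with ξ₀ = μB₀/k_BT (we use B₀ = μ₀H₀ so the energy ratio is dimensionally
clean), Ω = f·τ_B, τ_B = 3ηV/k_BT, and dW a 3-vector Wiener increment with
per-component variance dt\*. Both torque terms are perpendicular to **m**,
so |**m**| = 1 is conserved by the continuous dynamics.

Assumptions and exclusions: no Néel (internal) relaxation, no interparticle
interactions, no magnetic anisotropy energy, temperature-independent
viscosity. Core and hydrodynamic radii are statistically independent.

### Stochastic convention

The noise is multiplicative, so the integration convention matters. The
two-stage Heun scheme (same Gaussian draw in predictor and corrector)
converges to the **Stratonovich** solution, which is the physically correct
choice here: it is the convention under which the static-field stationary
state is the Boltzmann distribution, giving ⟨m_z⟩ = L(ξ) = coth ξ − 1/ξ.
The test suite asserts this equilibrium within Monte-Carlo error at
ξ ∈ {0.5, 1, 2, 5}, and checks linear response against the Debye form at
three frequencies — together these pin both the drift/noise ratio and the
absolute relaxation timescale. An independent Legendre-hierarchy
Fokker–Planck solution of the same model was used during development as an
exact oracle for mean traces; the simulator agrees with it within
Monte-Carlo error.

### Integrator details

* **Renormalization.** Discrete steps let |**m**| drift (O(10⁻⁵) per step at
  the default step); each corrector output is projected back to the unit
  sphere. Step-halving on noise-free runs confirms second-order convergence
  of the projected scheme.
* **Time step.** dt\* = min(0.01·Ω_min, 10⁻³, Ω/ξ₀ per particle), rounded so
  an integer number of steps covers one drive period (making the
  rectangular-window FFT an exact quadrature in steady state). The
  0.01·Ω term resolves the relaxational timescale; the 10⁻³ cap guarantees
  ≥1000 steps per period; the Ω/ξ₀ term caps the deterministic rotation at
  0.5 rad per step for strongly driven ensembles. A convergence study at
  ξ₀ = 10³ shows harmonics move by <0.1% between dt\* = 10⁻³ and 5×10⁻⁵,
  so the cap is conservative.
* **Transient.** Orientations start uniform on the sphere (configurable:
  aligned-z, or equatorial — the latter for noise-free attractor analyses,
  where uniform initialization leaves near-pole stragglers that escape the
  unstable pole only logarithmically slowly). max(2, ⌈3·Ω_max⌉) drive
  periods are discarded: relaxation occupies ~Ω periods in t\* units.
* **Reproducibility.** One master `numpy` Generator per run, with a
  documented draw order: particle radii first, initial orientations second,
  then a single spawned integer seeds the noise Generator consumed
  particle-major inside the compiled kernel. Identical configuration + seed
  gives bit-identical traces. The ensemble loop is a numba kernel; a pure
  numpy reference implementation of the single step is exposed as
  `heun_step` and a test verifies the two paths agree bit-for-bit,
  including the noise stream.

### Ensembles and statistics

All particles integrate in one pass with per-particle (ξ₀, Ω) derived from
lognormally sampled core and hydrodynamic radii (moment-matched: sample mean
and sd converge to the specified m_r, s_r; default s_r = 0.10·m_r). The
kernel accumulates the ensemble mean and variance of m_z per time step
(pointwise standard errors) plus ten contiguous-block means, from which
standard errors of nonlinear spectral statistics are estimated
(block-resampling). Because |F_l| is a magnitude, harmonics far below the
Monte-Carlo noise floor are biased upward by ~the noise level; spectra meant
to resolve small amplitudes should use longer analysis windows (the
linear-response tests use 8 periods instead of the default 2).

## Spectroscopy conventions

F_l = (1/T_w)∫ m_z e^{i2πlt\*} dt\* over an integer number T_w of
steady-state periods; a_l = l·|F_l| (the factor l converts to the derivative
harmonic a pickup coil measures, the phase is discarded, and the 1/T_w
normalization makes a_l window-length independent). With this convention
sin(2πt\*) has a₁ = 1/2 and the saturated square wave has a_l = 2/π at every
odd l. The ensemble is averaged first, then transformed.

## Master-variable analyses

* **Sweeps** vary one physical knob — field amplitude B₀, viscosity (i.e.
  relaxation time), or frequency — holding one sampled ensemble fixed, and
  record A = ⟨ξ₀⟩/⟨Ω⟩ recomputed from the adjusted physical parameters.
  The default base frequency sets ⟨Ω⟩ = 1. For full master-curve studies
  (the `fig6`/`fig7` recipes and the acceptance script) the default grid
  is 15 log-spaced points over A ∈ [0.1, 10⁴]: harmonics
  only saturate near ξ₀ ~ 10³, and the one-parameter Langevin fit
  presupposes sigmoids swept through saturation — with a grid truncated at
  A = 100 the highest harmonics are still rising and their fit quality
  drops to R² ≈ 0.95.
* **Collapse metric**: normalized curves interpolated linearly in log A onto
  the grid overlap; reported as max and RMS absolute deviation plus the
  pointwise deviation in pooled standard-error units.
* **Validity regime.** The collapse of the mean dynamics under
  (ξ₀, Ω) → (cξ₀, cΩ) is approximate: the stochastic relaxation rate 1/Ω is
  not scale-invariant. Quantitatively (established against the exact
  Fokker–Planck solution): the residual deviation at fixed ξ₀/Ω *halves*
  with each doubling of Ω, while at fixed Ω it *grows* with ξ₀ because the
  saturation flip is noise-timed, making pointwise trace comparisons in deep
  saturation resolvable at any realistic ensemble size. The collapse tests
  therefore run at Ω > 1 and moderate amplitude (trace pair ξ₀ = 6, Ω = 3
  vs doubled; harmonic curves at Ω = 3 vs 6 over A ∈ [1, 12], the amplitude
  range of typical MSB experiments), where the intrinsic deviation is well
  below Monte-Carlo error at n = 10⁴. A property test asserts the monotone
  improvement of collapse quality with Ω.
* **Langevin master fit**: a_l/max a_l ≈ L(b_l A), single parameter b_l,
  unweighted least squares (Monte-Carlo SEs are reported, not used as
  weights), optimizer seeded by a coarse log-grid scan and polished by
  bounded scalar minimization; L evaluated with the series x/3 − x³/45 for
  |x| < 10⁻⁴. R² = 1 − SS_res/SS_tot.
* **Sensitivity**: dL/d(log A) is maximal at x\* ≈ 1.911 (located as the
  root of the analytic derivative — the maximum itself is flat), so the
  steepest-slope operating point is A\* = x\*/b_l on the fitted curve;
  against A on a linear axis the slope is maximal at the low-A end, so the
  log-axis inflection is the operative definition. Both are reported.
* **Temperature suite**: T enters ξ₀ and Ω identically (∝ 1/T), so fixed-A
  runs across 250–350 K share mean dynamics; the suite reports the max
  pairwise deviation across temperatures in pooled-SE units. "Fluctuations
  about the mean" are quantified two ways: the across-temperature variance
  of the mean traces (what a figure shows, but a ~45%-noise estimator with
  ten degrees of freedom) and the time-averaged per-particle variance
  (whose expectation is n times the former, estimated precisely from all
  particles); the monotone decrease of fluctuations with A is asserted on
  the latter. Defaults: Ω_ref = 3 at T_ref = 300 K, A ∈ {2, 4, 8}.

## Debye module

The linear-response closed form and its limits serve as analytic
cross-checks. The low-frequency expansion keeps the O(Ω) quadrature term
(ξ₀/3)·2πΩ sin 2πt\* — the binomial expansion of 1/(1+(2πΩ)²) has no linear
term, so this is the mathematically forced truncation — whose amplitude is
proportional to the field-frequency product, the "slew rate". The
high-frequency limit (A/6π) sin 2πt\* is recovered from the full form to
within 1% for Ω ≥ 10.

## Synthetic data and external validity

All inputs are generated by the package itself (sampled ensembles, seeded
noise); no measured spectra ship with it. The generator reproduces the
statistical structure of typical MSB tracer suspensions — lognormal core
and hydrodynamic sizes at 10% coefficient of variation, saturation
magnetization 250 kA/m, water-like viscosity, room temperature — but not
features of real data such as Néel contributions from small cores, particle
aggregation and interaction fields, coil noise floors, or field
inhomogeneity. Passing tests therefore validate the rotational-diffusion
model and its scaling structure, not any particular instrument; the
harmonic-ratio (r₅₃) analysis path accepts externally measured spectrum
tables with the same CSV schema for that purpose.

## Problem sizes

Default test-scale runs use 10⁴ particles (10⁵ is configurable and changes
only Monte-Carlo error), 2 analysis periods, and the step rule above; the
full master-curve study (15 A values, 5 harmonics) completes in a few
minutes on one CPU. Statistical tolerances in the test suite are stated in
pooled standard-error units (typically 4 SE) so they scale correctly with
ensemble size.

## Known limitations

* Bit-level reproducibility is per numba version (the compiled kernel
  consumes the Generator stream directly).
* Harmonic magnitudes below the Monte-Carlo floor are biased upward
  (magnitude of a noisy complex number); ratios of such harmonics are
  unreliable.
* The master-variable collapse is a controlled approximation, not an
  identity — see the validity-regime discussion above for when pointwise
  agreement within Monte-Carlo error can be expected.
* The Langevin master fit is phenomenological; its parameters b_l have no
  derived microscopic meaning, and the fit is least accurate near the
  sigmoid foot (low A).
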