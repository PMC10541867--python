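# Methods

## Model overview

`planktonpatch` follows a single body of water (a "Lagrangian patch") in a
frame co-moving and co-rotating with it, so only deformation and exchange
matter.  Three coupled blocks form the state:

1. **Geometry.** The patch is an ellipse; `W` and `L` are the standard
   deviations of an idealised dye distribution along the contracting and
   stretching axes (so `2W` is the physical patch width), `S = W + L` and
   `A = πWL`.  Incompressible strain `γ` conserves area; diffusion `κ`
   grows both squared axes at `2κ` and is therefore the sole source of
   dilution, at rate `dA/dt = πκ(W²+L²)/(WL) ≥ 2πκ`.  The integrated
   variables are `(W², L²)`, the natural variables of the linear ODEs;
   square roots are taken on demand.  If a user supplies `W > L` the axes
   are swapped at construction so `W` is always the contracting one.
2. **Tracer moments.** Each tracer (iron resource `r`, phytoplankton `b`
   in iron currency) is split into patch-interior spatial mean and
   fluctuation.  The state carries two means, two variances and the
   covariance.  The surrounding is a mean-field reservoir with constant
   moments (background means, zero second moments by default; a "desert"
   configuration with all-zero surroundings is expressible through the
   config system).
3. **Biology.** Monod uptake `νrb/(r+k)`, linear mortality `m·b`, a
   remineralised fraction `α` returned to the resource.  The nonlinear
   uptake is closed at second order: third central moments are dropped,
   leaving the variance of `r` to depress and the `r–b` covariance to
   enhance the mean uptake.

## Process terms

With dilution rate `λ = (dA/dt)/A`:

* means: `d⟨p_i⟩/dt = λ(⟨s_i⟩ − ⟨p_i⟩) + reactions` — equivalent to exact
  tracer-mass conservation `d(A⟨p_i⟩)/dt = (dA/dt)⟨s_i⟩`;
* second moments: `d⟨p_i′p_j′⟩/dt = λ[(⟨s_i′s_j′⟩ − ⟨p_i′p_j′⟩) +
  (⟨s_i⟩−⟨p_i⟩)(⟨s_j⟩−⟨p_j⟩)] − (κ/S²)⟨p_i′p_j′⟩ + reactions`.

The entrainment terms are the continuum limit of pooling the patch with an
infinitesimal ring of entrained surrounding water; the test suite rebuilds
that merge from explicit finite samples and verifies the tendencies to
second order in the area increment.  The internal-mixing decay applies the
same rate `κ/S²` to variances and covariance; an O(1) prefactor in this
rate is not constrained by the underlying scale argument and is taken as
exactly 1.

Consequences worth knowing: entrainment with a constant surrounding
conserves the *absolute* anomaly `A(⟨p_b⟩−⟨s_b⟩)` exactly, so dilution
affects the biomass budget only through the biology (nutrient smearing vs
covariance generation); and entrainment of water with a different mean
always *creates* variance, even in an initially homogeneous patch.

## Parameters and defaults

| symbol | meaning | default | units |
|---|---|---|---|
| γ₀ | strain at initial size | 0.12 | day⁻¹ |
| κ₀ | diffusivity at initial size | 0.1 | km² day⁻¹ |
| S₀ | initial patch size (diameter of the initial circle) | 10 | km |
| strain exponent | γ ∝ S^exp | −2/3 | — |
| diffusivity exponent | κ ∝ S^exp | +1 | — |
| ν | maximum growth rate | 1.05 | day⁻¹ |
| k | half-saturation constant (iron) | 2 | μmol m⁻³ |
| m | linear mortality | 0.05 | day⁻¹ |
| m′ | quadratic mortality (optional) | 0 | (μmol m⁻³)⁻¹ day⁻¹ |
| α | remineralised fraction | 0 | — |
| Fe:C | iron-to-carbon molar ratio | 10⁻⁵ | — |
| h | patch thickness | 10 | m |
| τ | integration window | 30 (42 for the SOIREE preset) | day |
| dt | time step | 0.01 (≈ 14 min) | day |

The scaling exponents encode observed submesoscale behaviour over the
10–100 km range: strain weakens as the filament grows (−2/3 power),
eddy diffusivity grows linearly with scale.  The prefactors are derived,
not stored: the laws pass exactly through (S₀, γ₀) and (S₀, κ₀), so the
axes of an ensemble sweep are the physically observable initial rates.
Both presets (`soiree_config`, `default_ensemble_config`) apply the
scaling laws throughout the run.

The background iron concentration (0.1 μmol m⁻³) equals the biological
steady state `r* = mk/(ν−m)` of the default rates, so the surrounding
biomass is stationary by construction.  With α = 0 the surrounding
*resource* equation is not strictly stationary (uptake is uncompensated);
the surrounding is a held-constant reservoir by assumption, and the exact
fixed point of the tracer subsystem exists only at α = 1 — the test suite
checks stationarity accordingly.

## Numerical choices

* **Integrator:** fixed-step classical RK4.  The system is smooth and
  non-stiff over the explored parameter ranges; at dt = 0.01 day the
  solution agrees with an adaptive high-order reference (DOP853 at
  rtol 1e−10) to ~1e−11 relative, and halving dt moves the LBA by far
  less than 0.1%.  A fixed step keeps trajectories bit-deterministic.
* **Admissibility guard:** a discrete step can, in principle, push a
  variance below zero or the covariance past the Cauchy–Schwarz bound
  even though the continuous flow cannot.  After each step variances are
  clipped at 0 and `|cov|` clamped to `√(var_r·var_b)`; clamps are
  counted on the trajectory (`n_psd_clamps`).  In all default
  experiments the guard never fires — the dynamics ride close to, but
  inside, the correlation-1 boundary.
* **Well-mixed mode** pins all second moments to zero (state and
  tendencies), which reduces the biology exactly to its mean-field form;
  it is not a separate implementation.  Geometry is independent of the
  tracers, so paired well-mixed/heterogeneous runs share identical
  dilution histories.
* **Quadrature:** metrics use the trapezoidal rule on the simulation
  grid, consistent with the integrator's accuracy.
* **Mg C conversion:** `(μmol Fe m⁻³)·km² × h[m] × 10⁶ m²/km² × 10⁻⁶
  mol/μmol ÷ (Fe:C) × 12 g/mol × 10⁻⁶ Mg/g`; with the defaults, 1 unit of
  raw anomaly integral = 12 Mg C.
* **Ensembles** default to log-spaced axes over [0.01, 0.6] (both
  day⁻¹ and km² day⁻¹), resolving the low-dilution structure of the
  LBA-versus-dilution curve; the acceptance script uses a 12×12 grid
  (288 runs), sized to finish in well under a minute while the maximum
  excess — attained at the grid corner, which every resolution contains —
  is resolution-independent.

## Design choices made where the design was open

* **Quadratic-mortality closure.** The mean-equation loss is the exact
  identity `⟨m′b²⟩ = m′(⟨b⟩² + var_b)`.  For the fluctuation equations no
  canonical closure exists at this truncation order; we substitute the
  linearised rate `2m′⟨b⟩` for `m` in every second-moment mortality term
  (var_b loss `−4m′⟨b⟩var_b`, covariance loss `−2m′⟨b⟩cov`, var_r gain
  `+2αm′⟨b⟩cov`).  The mean equation is oracle-tested by sampling; the
  second-moment terms are a documented modelling choice.
* **Ellipse/area identification.** The dye-variance ellipse is identified
  directly with the patch (`A = πWL`) rather than scaled to contain a
  fixed fraction of the dye.
* **Initial circle.** "10 km across" is read as `W(0) = L(0) = 5` km, so
  the physical width `2W = 10` km and the size `S = 10` km hold
  simultaneously; initial area ≈ 78.54 km².

## What the simulations do and do not show

The model is a deterministic moment truncation, not a turbulence
simulation: it cannot represent non-Gaussian patchiness, multi-scale
variance cascades, evolving surroundings, vertical exchange, explicit
grazers or active behaviour.  Conclusions about heterogeneity effects
rest on the second-order closure being adequate, which the Monte-Carlo
closure oracle in the tests supports only at small-to-moderate relative
fluctuation levels.  Two structural features deserve emphasis when
comparing with coarse summaries of similar experiments:

* Because entrainment conserves the absolute anomaly when the
  surrounding is fixed at the biomass-replacement level `r*`, mild
  dilution can *slightly raise* the well-mixed LBA over a 30-day window
  (entrained nutrient freezes the anomaly that a closed patch would lose
  to mortality) before the smearing penalty dominates.  The well-mixed
  LBA maximum on the default grid therefore sits ~2.5% above the
  low-strain/low-diffusion corner value, at (γ₀ ≈ 0.2, κ₀ = 0.01) — a
  ridge far below heat-map visibility.
* On the default 12×12 grid the heterogeneous ensemble's LBA exceeds the
  well-mixed one by up to ≈360% (at the high-strain/high-diffusion
  corner).  The qualitative contrast — monotone decline versus interior
  maximum against dilution — is robust to grid resolution, time step and
  the mixing prefactor.

## Known limitations

Single patch, single resource, single consumer; constant thickness (no
vertical dynamics); surroundings never deplete; second moments of the
surrounding fixed; closure accuracy degrades as fluctuations approach the
means; quadratic-mortality second-moment terms are a stand-in truncation.
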