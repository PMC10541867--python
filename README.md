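# planktonpatch

Lagrangian patch model of plankton bloom dynamics under strain, diffusion
and dilution-generated patchiness.

## The problem

A localized nutrient injection in the ocean — a dust deposition, an eddy
upwelling event, a deliberate iron release — creates a drifting water
patch whose fate is set jointly by physics and biology.  Horizontal strain
stretches the patch into a filament; small-scale turbulent diffusion
dilutes it into the surrounding water and mixes its interior.  Classical
Lagrangian treatments assume the patch stays well mixed, but dilution
itself creates spatial heterogeneity: entrained water differs in
composition from the patch core, producing variance in tracer fields and,
crucially, a positive spatial covariance between nutrient and plankton.
Because nutrient uptake is nonlinear, this patchiness feeds back on the
patch-mean biology.

`planktonpatch` is a deterministic simulator for this coupled system,
aimed at biological oceanographers and modellers studying bloom dynamics,
fertilisation experiments and sub-grid patchiness effects.

## The model

The patch is an ellipse with half-axes `W` (contracting) and `L`
(stretching), size `S = W + L` and area `A = πWL`, evolving as

```
d(W²)/dt = +2κ − 2γW²        d(L²)/dt = +2κ + 2γL²
dA/dt    = πκ (W² + L²)/(WL)
```

with size-dependent forcing `γ(S) = γ₀ (S/S₀)^(−2/3)` and
`κ(S) = κ₀ (S/S₀)`.  Each tracer field is Reynolds-decomposed,
`p = ⟨p⟩ + p′`, and the state carries the means `⟨p_r⟩, ⟨p_b⟩`
(iron resource and phytoplankton in iron currency), the variances and the
covariance `⟨p_r′p_b′⟩`.  Three processes sum into their tendencies:

* **entrainment** at the relative dilution rate `(dA/dt)/A`, relaxing
  moments toward the (mean-field, constant) surrounding and producing
  second moments from mean contrasts `(⟨s_i⟩−⟨p_i⟩)(⟨s_j⟩−⟨p_j⟩)`;
* **internal mixing**, decaying all second moments at rate `κ/S²`;
* **reactions**: Monod uptake `ν⟨p_r⟩⟨p_b⟩/(⟨p_r⟩+k)`, linear mortality
  `m⟨p_b⟩` with remineralised fraction `α`, closed at second order so the
  resource variance depresses and the covariance enhances mean growth.

The system is integrated with fixed-step RK4 (dt = 0.01 day).  The
headline diagnostic is the Lagrangian biomass anomaly
`LBA = (1/τ)∫ A(t)(⟨p_b⟩−⟨s_b⟩) dt`, converted to Mg C via the patch
thickness and the Fe:C ratio; `m(1−α)·LBA` is the mean export-rate
anomaly.  A two-subregion analytical model (`growth_gap`) gives the exact
condition under which patchiness accelerates growth:
`(k+r)δb > b·δr`.

## Worked example

```python
import numpy as np
from planktonpatch import run_simulation, soiree_config

traj = run_simulation(soiree_config())   # 42-day iron-release preset
i = int(np.argmax(traj.mean_b))
print(traj.time[i], traj.mean_b[i] / 0.0249)
```

prints `13.79 16.11`: the simulated bloom peaks on day ~14 at ~16 times
the surrounding biomass concentration, consistent with the observed
timing and amplitude of the Southern Ocean iron-release bloom the preset
emulates.  The same run from the shell, plus an ensemble sweep:

```
$ planktonpatch soiree --out soiree
bloom peak day 13.79, peak/surrounding ratio 16.11
$ planktonpatch ensemble --grid 8 8 --out ens
well-mixed max LBA 373.0 Mg C; heterogeneous max LBA 539.6 Mg C
max percent excess 362%
```

The well-mixed ensemble loses biomass anomaly with increasing dilution,
while the heterogeneous ensemble peaks at intermediate dilution — the
signature of dilution-driven patchiness enhancing growth.  The
`examples/` directory holds one short narrative script per capability
(`run_soiree.py`, `ensemble_contrast.py`, `two_box_gap.py`,
`dilution_and_export.py`).

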