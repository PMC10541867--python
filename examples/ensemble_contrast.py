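"""Contrast well-mixed and heterogeneous patches across strain and diffusion.

Runs paired ensembles on a small log-spaced (gamma0, kappa0) grid and
compares the Lagrangian biomass anomaly (LBA, in Mg C) cell by cell.  The
well-mixed runs pin all spatial second moments to zero; the heterogeneous
runs let dilution generate variance and covariance.
"""

import numpy as np

from planktonpatch import default_ensemble_config, log_grid, run_ensemble

grid = run_ensemble(log_grid(8), log_grid(8), default_ensemble_config(tau=30.0))
wm = grid.lba["well_mixed"]
het = grid.lba["heterogeneous"]
excess = 100.0 * (het - wm) / wm

print(f"well-mixed LBA:    {wm.min():.0f} .. {wm.max():.0f} Mg C (always positive)")
print(f"heterogeneous LBA: {het.min():.0f} .. {het.max():.0f} Mg C")
print(f"max percent excess of heterogeneity: {excess.max():.0f}%")

dil = grid.dilution["heterogeneous"].ravel()
order = np.argsort(dil)
curve = het.ravel()[order]
print(f"dilution factors span {dil.min():.2f} .. {dil.max():.0f}")
print(f"heterogeneous LBA vs dilution peaks at dilution {dil[order][np.argmax(curve)]:.0f} "
      f"(interior maximum: {0 < np.argmax(curve) < len(curve) - 1})")

# Dilution hurts a well-mixed patch (it smears the nutrient pulse) but a
# diluting patch that is allowed to be patchy converts mean contrasts into
# positive resource-biomass covariance, which accelerates growth enough to
# make intermediate dilution the most productive regime.
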