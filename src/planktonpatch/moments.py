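"""Entrainment and internal-mixing tendencies of tracer spatial moments.

Each tracer field inside the patch is Reynolds-decomposed into a spatial
mean plus a fluctuation, ``p = <p> + p'``.  The patch state is then the
vector of first moments (means) and second central moments (variances and
the resource-biomass covariance).

Two physical processes act on these moments:

* **Entrainment** — as the patch area grows at rate dA/dt, surrounding
  water is incorporated.  Means relax toward the surrounding means at the
  relative dilution rate (dA/dt)/A.  Second moments relax toward the
  surrounding second moments *plus* a production term: mixing in water
  whose mean differs from the patch mean necessarily creates variance,
  ``(<s_i>-<p_i>)(<s_j>-<p_j>)``.

* **Internal mixing** — sub-patch-scale stirring homogenises the interior,
  decaying every second moment at rate kappa/S^2 while leaving means
  untouched.

The surrounding is a mean-field reservoir: its moments are held constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "TracerMoments",
    "SurroundingState",
    "entrainment_mean_tendency",
    "entrainment_comoment_tendency",
    "mixing_tendency",
    "clamp_psd",
]


@dataclass(frozen=True)
class TracerMoments:
    """Patch-interior spatial moments of resource (r) and biomass (b).

    Means in umol m^-3 (biomass in iron currency), co-moments in
    (umol m^-3)^2.  Valid states have non-negative means and variances and
    satisfy Cauchy-Schwarz, cov_rb^2 <= var_r*var_b.
    """

    mean_r: float
    mean_b: float
    var_r: float = 0.0
    var_b: float = 0.0
    cov_rb: float = 0.0

    def validate(self, atol: float = 1e-12) -> None:
        if self.mean_r < -atol or self.mean_b < -atol:
            raise ValueError(f"negative tracer mean: {self}")
        if self.var_r < -atol or self.var_b < -atol:
            raise ValueError(f"negative tracer variance: {self}")
        if self.cov_rb**2 > self.var_r * self.var_b * (1.0 + 1e-9) + atol:
            raise ValueError(f"covariance violates Cauchy-Schwarz: {self}")


@dataclass(frozen=True)
class SurroundingState:
    """Mean-field moments of the water surrounding the patch (constant in time)."""

    mean_r: float
    mean_b: float
    var_r: float = 0.0
    var_b: float = 0.0
    cov_rb: float = 0.0


def entrainment_mean_tendency(p_mean: float, s_mean: float, A: float, dAdt: float) -> float:
    """d<p>/dt from dilution: (dA/dt / A) * (<s> - <p>), umol m^-3 day^-1.

    Equivalent to mass conservation of the merge of the patch (area A) with
    an infinitesimal ring of surrounding water (area dA): d(A<p>)/dt =
    (dA/dt)<s>.
    """
    if A <= 0:
        raise ValueError(f"patch area must be positive, got A={A}")
    return dAdt / A * (s_mean - p_mean)


def entrainment_comoment_tendency(
    p_com: float,
    s_com: float,
    p_mean_i: float,
    p_mean_j: float,
    s_mean_i: float,
    s_mean_j: float,
    A: float,
    dAdt: float,
) -> float:
    """Second-moment tendency from dilution, (umol m^-3)^2 day^-1.

    (dA/dt / A) * [ (s_com - p_com) + (<s_i>-<p_i>)(<s_j>-<p_j>) ].
    For i = j the production term is a square: entraining water with a
    different mean always generates variance, even from a perfectly
    homogeneous patch.
    """
    if A <= 0:
        raise ValueError(f"patch area must be positive, got A={A}")
    production = (s_mean_i - p_mean_i) * (s_mean_j - p_mean_j)
    return dAdt / A * ((s_com - p_com) + production)


def mixing_tendency(p_com: float, kappa: float, S: float) -> float:
    """Internal-mixing decay of a second moment: -(kappa/S^2) * p_com.

    The same rate applies to variances and the covariance; the decay only
    shrinks magnitudes and never flips signs.
    """
    if S <= 0:
        raise ValueError(f"patch size must be positive, got S={S}")
    return -kappa / S**2 * p_com


def clamp_psd(mom: TracerMoments) -> tuple[TracerMoments, bool]:
    """Project moments back onto the admissible cone after a discrete step.

    Clips negative variances to zero and clamps the covariance to
    |cov| <= sqrt(var_r*var_b).  The continuous equations preserve these
    constraints but a finite step may overshoot.  Returns the (possibly)
    corrected moments and whether any clamp fired.
    """
    var_r = max(mom.var_r, 0.0)
    var_b = max(mom.var_b, 0.0)
    bound = math.sqrt(var_r * var_b)
    cov = min(max(mom.cov_rb, -bound), bound)
    clamped = (var_r != mom.var_r) or (var_b != mom.var_b) or (cov != mom.cov_rb)
    if clamped:
        return replace(mom, var_r=var_r, var_b=var_b, cov_rb=cov), True
    return mom, False
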