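"""Moment-closed resource-consumer kinetics (Monod uptake, mortality).

The biology couples an inorganic resource (iron, ``r``) to a planktonic
consumer (``b``, carried in iron currency via the Fe:C ratio).  The
mean-field kinetics are::

    dr/dt = -nu * r*b/(r+k) + alpha*m*b
    db/dt = +nu * r*b/(r+k) - m*b

with maximum growth rate ``nu``, half-saturation ``k``, linear mortality
``m`` and remineralised fraction ``alpha``.  Because Monod uptake is
nonlinear, spatial heterogeneity feeds back on the means: expanding the
uptake to second order in the fluctuations yields closed tendencies for
the five moments (mean_r, mean_b, var_r, var_b, cov_rb) in which the
resource variance *depresses* and a positive resource-biomass covariance
*enhances* mean growth — the mechanism by which dilution-generated
patchiness can amplify a bloom.

An optional quadratic mortality ``m' * b^2`` emulates grazing pressure;
its mean-equation closure ``<m' b^2> = m'(<b>^2 + var_b)`` is exact, the
second-moment terms use the same third-central-moment truncation as the
linear-mortality closure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .moments import TracerMoments

__all__ = [
    "BioParams",
    "MomentTendencies",
    "reaction_tendencies",
    "quadratic_mortality_tendencies",
    "steady_state_resource",
]


@dataclass(frozen=True)
class BioParams:
    """Biological parameters of the resource-consumer pair.

    Defaults are the iron-limited Southern Ocean bloom setting:
    nu=1.05 day^-1, m=0.05 day^-1, k=2 umol m^-3, alpha=0 (no recycling),
    Fe:C = 1e-5.
    """

    nu: float = 1.05
    k: float = 2.0
    m: float = 0.05
    alpha: float = 0.0
    mortality_form: Literal["linear", "quadratic"] = "linear"
    m_quad: float = 0.0  # (umol m^-3)^-1 day^-1, quadratic form only
    fe_to_c: float = 1e-5

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.m < 0 or self.m_quad < 0:
            raise ValueError("mortality rates must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.fe_to_c <= 0:
            raise ValueError("fe_to_c must be positive")
        if self.mortality_form not in ("linear", "quadratic"):
            raise ValueError(f"unknown mortality_form {self.mortality_form!r}")


@dataclass(frozen=True)
class MomentTendencies:
    """Right-hand sides for the five tracer moments."""

    mean_r: float
    mean_b: float
    var_r: float
    var_b: float
    cov_rb: float


def reaction_tendencies(mom: TracerMoments, params: BioParams) -> MomentTendencies:
    """Moment-closed reaction tendencies with linear mortality.

    The closure drops third central moments.  The mean tendencies sum to
    (alpha-1)*m*<b> — the biomass export flux — so with alpha=1 reactions
    conserve total tracer <r>+<b> identically.
    """
    nu, k, m, alpha = params.nu, params.k, params.m, params.alpha
    r, b = mom.mean_r, mom.mean_b
    vr, vb, cov = mom.var_r, mom.var_b, mom.cov_rb
    d = r + k  # Monod denominator

    uptake = nu * r * b / d - nu * k * b * vr / d**3 + nu * k * cov / d**2

    d_mean_r = -uptake + alpha * m * b
    d_mean_b = uptake - m * b
    d_var_r = (
        -2.0 * nu * k * b * vr / d**2
        - 2.0 * nu * r * cov / d
        + 2.0 * alpha * m * cov
    )
    d_var_b = (
        2.0 * nu * r * vb / d
        + 2.0 * nu * k * b * cov / d**2
        - 2.0 * m * vb
    )
    d_cov = (
        nu * r / d * (cov - vb)
        + nu * k * b / d**2 * (vr - cov)
        + m * (alpha * vb - cov)
    )
    return MomentTendencies(d_mean_r, d_mean_b, d_var_r, d_var_b, d_cov)


def quadratic_mortality_tendencies(mom: TracerMoments, params: BioParams) -> MomentTendencies:
    """Moment-closed tendencies with quadratic mortality m'*b^2.

    The mean biomass loss is the exact second-moment expansion
    ``m'(<b>^2 + var_b)``; in the fluctuation equations the linear rate m
    is replaced by the linearised quadratic rate 2*m'*<b> (third central
    moments dropped, as in :func:`reaction_tendencies`).
    """
    if params.mortality_form != "quadratic":
        raise ValueError("quadratic_mortality_tendencies requires mortality_form='quadratic'")
    nu, k, mq, alpha = params.nu, params.k, params.m_quad, params.alpha
    r, b = mom.mean_r, mom.mean_b
    vr, vb, cov = mom.var_r, mom.var_b, mom.cov_rb
    d = r + k

    uptake = nu * r * b / d - nu * k * b * vr / d**3 + nu * k * cov / d**2
    loss_mean = mq * (b**2 + vb)  # exact: <m' b^2>
    m_eff = 2.0 * mq * b  # linearised mortality rate for fluctuations

    d_mean_r = -uptake + alpha * loss_mean
    d_mean_b = uptake - loss_mean
    d_var_r = (
        -2.0 * nu * k * b * vr / d**2
        - 2.0 * nu * r * cov / d
        + 2.0 * alpha * m_eff * cov
    )
    d_var_b = (
        2.0 * nu * r * vb / d
        + 2.0 * nu * k * b * cov / d**2
        - 2.0 * m_eff * vb
    )
    d_cov = (
        nu * r / d * (cov - vb)
        + nu * k * b / d**2 * (vr - cov)
        + m_eff * (alpha * vb - cov)
    )
    return MomentTendencies(d_mean_r, d_mean_b, d_var_r, d_var_b, d_cov)


def steady_state_resource(params: BioParams) -> float:
    """Resource level r* = m*k/(nu - m) where Monod growth balances mortality.

    Only defined for linear mortality with nu > m.  With the default
    parameters r* = 0.05*2/1.0 = 0.1 umol m^-3 — the background iron level
    of a surrounding ocean whose biomass is stationary.
    """
    if params.mortality_form != "linear":
        raise ValueError("steady state defined for linear mortality only")
    if params.nu <= params.m:
        raise ValueError("no positive steady state: nu must exceed m")
    return params.m * params.k / (params.nu - params.m)
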