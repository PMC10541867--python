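"""Elliptical patch geometry under strain and diffusion.

A Lagrangian water patch is idealised as an ellipse with half-width ``W``
(contracting axis) and half-length ``L`` (expanding axis), both in km.  The
characteristic size is ``S = W + L`` and the associated surface area is
``A = pi * W * L``.  Horizontal strain stretches the ellipse while conserving
area; small-scale diffusion grows both axes and is the only process that
dilutes the patch into its surroundings.

The natural dynamical variables are the squared half-axes::

    d(W^2)/dt = +2*kappa - 2*gamma*W^2
    d(L^2)/dt = +2*kappa + 2*gamma*L^2

and the induced area growth (dilution) rate is::

    dA/dt = pi * kappa * (W^2 + L^2) / (W * L)

Strain and diffusivity follow turbulence-inspired scaling laws in patch
size: gamma ~ S^(-2/3) (Richardson-type inverse cascade of strain) and
kappa ~ S (scale-dependent eddy diffusivity), each anchored so the law
passes through the user-supplied value at the initial size S0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PatchShape",
    "ForcingLaws",
    "strain_at_size",
    "diffusion_at_size",
    "shape_tendency",
    "area_growth_rate",
]


@dataclass(frozen=True)
class PatchShape:
    """Ellipse half-axes in km; ``W`` is the minor (contracting) axis.

    If constructed with ``W > L`` the axes are swapped so the convention
    ``L >= W`` always holds (the aligned Lagrangian frame puts the
    contracting direction on the W axis).
    """

    W: float
    L: float

    def __post_init__(self) -> None:
        if not (self.W > 0 and self.L > 0):
            raise ValueError(f"half-axes must be positive, got W={self.W}, L={self.L}")
        if self.W > self.L:
            # enforce axis convention by swapping on construction
            w, length = self.L, self.W
            object.__setattr__(self, "W", w)
            object.__setattr__(self, "L", length)

    @property
    def S(self) -> float:
        """Characteristic patch size W + L, km."""
        return self.W + self.L

    @property
    def A(self) -> float:
        """Patch area pi*W*L, km^2."""
        return math.pi * self.W * self.L


@dataclass(frozen=True)
class ForcingLaws:
    """Size-dependent strain/diffusion laws anchored at the initial size.

    Parameters
    ----------
    gamma0 : float
        Strain rate at the reference size ``S0``, day^-1.
    kappa0 : float
        Diffusivity at the reference size ``S0``, km^2 day^-1.
    S0 : float
        Reference (initial) patch size, km.
    strain_exponent, kappa_exponent : float
        Power-law exponents; defaults -2/3 and +1.  The prefactors are
        derived so the laws pass exactly through (S0, gamma0) and
        (S0, kappa0).
    """

    gamma0: float
    kappa0: float
    S0: float
    strain_exponent: float = -2.0 / 3.0
    kappa_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma0 < 0:
            raise ValueError("gamma0 must be non-negative")
        if self.kappa0 < 0:
            raise ValueError("kappa0 must be non-negative")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")


def strain_at_size(forcing: ForcingLaws, S: float) -> float:
    """Strain rate gamma(S) = gamma0 * (S/S0)**strain_exponent, day^-1."""
    if S <= 0:
        raise ValueError(f"patch size must be positive, got S={S}")
    return forcing.gamma0 * (S / forcing.S0) ** forcing.strain_exponent


def diffusion_at_size(forcing: ForcingLaws, S: float) -> float:
    """Diffusivity kappa(S) = kappa0 * (S/S0)**kappa_exponent, km^2 day^-1."""
    if S <= 0:
        raise ValueError(f"patch size must be positive, got S={S}")
    return forcing.kappa0 * (S / forcing.S0) ** forcing.kappa_exponent


def shape_tendency(shape: PatchShape, gamma: float, kappa: float) -> tuple[float, float]:
    """Time derivatives (d(W^2)/dt, d(L^2)/dt) in km^2 day^-1.

    With kappa=0 these ODEs conserve the product W*L (hence the area):
    W shrinks as exp(-gamma t) while L grows as exp(+gamma t).
    """
    dW2 = 2.0 * kappa - 2.0 * gamma * shape.W**2
    dL2 = 2.0 * kappa + 2.0 * gamma * shape.L**2
    return dW2, dL2


def area_growth_rate(shape: PatchShape, kappa: float) -> float:
    """Dilution rate dA/dt = pi*kappa*(W^2+L^2)/(W*L), km^2 day^-1.

    Always >= 2*pi*kappa, with equality only for a circular patch; it is
    exactly the chain-rule derivative of A = pi*W*L under
    :func:`shape_tendency`, so strain alone never dilutes the patch.
    """
    return math.pi * kappa * (shape.W**2 + shape.L**2) / (shape.W * shape.L)
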