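"""Finger spacing of the diffusion-limited growth instability.

When the line tension of a growing liquid-condensed domain drops, its
boundary becomes unstable to a Mullins-Sekerka fingering instability:
the DPPC concentration gradient in the melt is compressed at finger
tips and stretched in the troughs, so protrusions grow.  Line tension
opposes short wavelengths.  The marginal (critical) wavenumber is

    k0 = 1 / sqrt(2 l_C l_D)

with capillary length l_C = lambda / (alpha_L dGamma^2) and diffusion
length l_D = D_L / v; the fastest-growing mode is k* = k0 / sqrt(3) and
the predicted finger spacing is d ~ 1/k* = sqrt(6 l_C l_D).

Convention: spacing is the reciprocal wavenumber d = 1/k*, not
2*pi/k*.  For diffusive growth of a cylindrical crystal the diffusion
length is replaced by the cylinder radius R.

Units are the caller's, provided they are consistent (lengths all in
one unit, times in one unit); outputs inherit them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GrowthFrontParams",
    "capillary_length",
    "diffusion_length",
    "critical_wavenumber",
    "fastest_wavenumber",
    "finger_spacing",
    "infer_capillary_length",
]

_SQRT3 = math.sqrt(3.0)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class GrowthFrontParams:
    """Material/kinetic parameters of the growing crystal front.

    Either (``D_L``, ``v``) or a cylinder radius ``R`` must be given to
    set the diffusion length; (``line_tension``, ``alpha_L``,
    ``delta_Gamma``) set the capillary length.  ``l_C``/``l_D`` may be
    supplied directly instead.
    """

    D_L: float | None = None  # DPPC diffusivity in the melt
    v: float | None = None  # crystal growth front velocity
    alpha_L: float | None = None  # free-energy convexity at the melt concentration
    delta_Gamma: float | None = None  # concentration jump crystal - melt (1/area)
    line_tension: float | None = None
    R: float | None = None  # cylinder radius (cylindrical-crystal variant)
    l_C: float | None = None
    l_D: float | None = None

    def capillary_length(self) -> float:
        if self.l_C is not None:
            _require_positive(l_C=self.l_C)
            return self.l_C
        if None in (self.line_tension, self.alpha_L, self.delta_Gamma):
            raise ValueError(
                "need l_C or (line_tension, alpha_L, delta_Gamma)"
            )
        return capillary_length(self.line_tension, self.alpha_L, self.delta_Gamma)

    def diffusion_length(self) -> float:
        if self.R is not None:
            # cylindrical-crystal variant: the cylinder radius replaces D/v
            _require_positive(R=self.R)
            return self.R
        if self.l_D is not None:
            _require_positive(l_D=self.l_D)
            return self.l_D
        if None in (self.D_L, self.v):
            raise ValueError("need R, l_D, or (D_L, v)")
        return diffusion_length(self.D_L, self.v)


def capillary_length(line_tension: float, alpha_L: float, delta_Gamma: float) -> float:
    """l_C = lambda / (alpha_L * delta_Gamma^2)."""
    _require_positive(
        line_tension=line_tension, alpha_L=alpha_L, delta_Gamma=delta_Gamma
    )
    return line_tension / (alpha_L * delta_Gamma**2)


def diffusion_length(D_L: float, v: float) -> float:
    """l_D = D_L / v."""
    _require_positive(D_L=D_L, v=v)
    return D_L / v


def critical_wavenumber(p: GrowthFrontParams) -> float:
    """Marginal wavenumber k0 = 1 / sqrt(2 l_C l_D)."""
    return 1.0 / math.sqrt(2.0 * p.capillary_length() * p.diffusion_length())


def fastest_wavenumber(p: GrowthFrontParams) -> float:
    """Fastest-growing wavenumber k* = k0 / sqrt(3)."""
    return critical_wavenumber(p) / _SQRT3


def finger_spacing(p: GrowthFrontParams) -> float:
    """Predicted finger spacing d = 1/k* = sqrt(6 l_C l_D)."""
    return math.sqrt(6.0 * p.capillary_length() * p.diffusion_length())


def infer_capillary_length(d: float, l_D: float) -> float:
    """Invert the spacing law: l_C = d^2 / (6 l_D)."""
    _require_positive(d=d, l_D=l_D)
    return d * d / (6.0 * l_D)
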