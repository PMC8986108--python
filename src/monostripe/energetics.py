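"""Free energy and stability of isolated circular monolayer domains.

A liquid-condensed (L_C) domain in a liquid-expanded (L_E) matrix is
described by two competing energies: the line tension ``lambda`` of the
phase boundary (favouring compact shapes) and the electrostatic
self-repulsion of the excess surface-normal dipole density ``mu``
(favouring extended shapes).  Only the ratio ``lambda/mu**2`` — the
inverse Bond number, with units of length once multiplied by nothing
(it is dimensionless here because both lambda and mu**2 carry
energy/length) — enters the equilibrium shape problem, together with a
molecular cutoff ``delta`` (~1 nm) below which the continuum dipole
integral is regularised.

Internal unit convention: all lengths are nanometres.  Helpers that
speak micrometres convert at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BondParameters",
    "CircularDomain",
    "circular_free_energy_per_molecule",
    "equilibrium_radius",
    "stability_window",
]

_E = math.e


@dataclass(frozen=True)
class BondParameters:
    """Material parameters of the dipole/line-tension competition.

    Parameters
    ----------
    lambda_over_mu2 : float
        Inverse Bond number, the ratio of line tension to squared dipole
        density difference.  Dimensionless and >= 0.
    delta : float, default 1.0
        Molecular dipole cutoff length in nm.
    line_tension, mu2 : float, optional
        Absolute line tension and squared dipole density difference
        (both energy/length).  Only needed when absolute energies are
        wanted; their ratio must agree with ``lambda_over_mu2``.
    """

    lambda_over_mu2: float
    delta: float = 1.0
    line_tension: float | None = None
    mu2: float | None = None

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.lambda_over_mu2 < 0:
            raise ValueError(
                f"lambda_over_mu2 must be >= 0, got {self.lambda_over_mu2}"
            )
        if (self.line_tension is None) != (self.mu2 is None):
            raise ValueError("supply both line_tension and mu2, or neither")
        if self.line_tension is not None and self.mu2 is not None:
            ratio = self.line_tension / self.mu2
            if not math.isclose(ratio, self.lambda_over_mu2, rel_tol=1e-12):
                raise ValueError(
                    "line_tension/mu2 = %g inconsistent with lambda_over_mu2 = %g"
                    % (ratio, self.lambda_over_mu2)
                )

    @property
    def absolute(self) -> bool:
        """True when absolute energy scales (lambda, mu2) are available."""
        return self.mu2 is not None


@dataclass(frozen=True)
class CircularDomain:
    """A circular L_C domain of radius ``r`` (nm) with molecular area ``a0`` (nm^2)."""

    r: float
    a0: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"radius must be positive, got {self.r}")
        if not self.a0 > 0:
            raise ValueError(f"a0 must be positive, got {self.a0}")

    @property
    def n_molecules(self) -> float:
        """Number of molecules pi r^2 / a0 in the domain."""
        return math.pi * self.r**2 / self.a0


def circular_free_energy_per_molecule(
    domain: CircularDomain, p: BondParameters
) -> float:
    """Free energy per molecule of an isolated circular domain.

    F/N = (2 a0 / r) * [lambda - mu^2 * ln(4 r / (e^2 delta))].

    When absolute scales are absent the dimensionless form
    (2 a0 / r) * [lambda/mu^2 - ln(4 r / (e^2 delta))] is returned,
    i.e. the energy in units of mu^2.
    """
    r, a0 = domain.r, domain.a0
    core = p.lambda_over_mu2 - math.log(4.0 * r / (_E**2 * p.delta))
    f = (2.0 * a0 / r) * core
    if p.absolute:
        f *= p.mu2
    return f


def equilibrium_radius(p: BondParameters) -> float:
    """Minimum-energy radius r0 = (e^3 delta / 4) exp(lambda/mu^2), in nm.

    Obtained from d(F/N)/dr = 0: strictly increasing in lambda/mu^2 and
    linear in delta.
    """
    return (_E**3 * p.delta / 4.0) * math.exp(p.lambda_over_mu2)


def stability_window(p: BondParameters) -> tuple[float, float]:
    """Radius window (r0/e, e^(1/3) r0) of stable circular domains.

    Below r0/e circular domains are unstable to coalescence; above
    e^(1/3) r0 they are unstable to elliptical (and higher-order)
    boundary distortions.  The window always brackets r0 and its ratio
    r_max/r_min = e^(4/3) is parameter independent.
    """
    r0 = equilibrium_radius(p)
    return (r0 / _E, _E ** (1.0 / 3.0) * r0)


def free_energy_profile(
    p: BondParameters,
    a0: float = 0.45,
    r_min: float | None = None,
    r_max: float | None = None,
    n: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """F/N on a log-spaced radius grid (nm), for plotting/diagnostics."""
    r0 = equilibrium_radius(p)
    lo = r_min if r_min is not None else r0 / 20.0
    hi = r_max if r_max is not None else r0 * 20.0
    radii = np.geomspace(lo, hi, n)
    energies = np.array(
        [
            circular_free_energy_per_molecule(CircularDomain(r=float(r), a0=a0), p)
            for r in radii
        ]
    )
    return radii, energies
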