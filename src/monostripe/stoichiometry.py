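"""Lever-rule mole balance for the condensed-phase area fraction.

DPPC cocrystallises with hexadecanol (HD) or palmitic acid (PA) at a
fixed integer stoichiometry n (DPPC molecules per HD/PA molecule) in
the liquid-condensed (L_C) phase, while excess DPPC and all the
dihydrocholesterol (DChol) remain in the liquid-expanded (L_E) melt.
For a spreading solution with N molecules of HD and b*N of DPPC plus a
DChol mole fraction j of all molecules, the phase areas per reference N
are

    A_B = N (a_HD + n a_DC)                      (condensed, dye-dark)
    A_R = N (b - n) a_DL + j (b + 1) / (1 - j) N a_c   (expanded, dye-bright)

and the L_C area fraction is phi = A_B / (A_B + A_R).  Because phi(b)
curves for different n are well separated, measured area fractions at a
few spreading ratios pin down the integer stoichiometry — n = 2 for the
DPPC:HD/PA system.

All molecular areas in nm^2.  The trace fluorescent dye (~0.75 mol%) is
ignored in the balance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MolecularAreas",
    "CompositionModel",
    "AreaFractionObservation",
    "StoichiometryFit",
    "phase_areas",
    "area_fraction",
    "area_fraction_curve",
    "fit_stoichiometry",
]


@dataclass(frozen=True)
class MolecularAreas:
    """Per-molecule interfacial areas (nm^2).

    Defaults are the isotherm/diffraction values for the DPPC + HD (or
    PA) + DChol system: ordered-phase HD/PA 0.2, DPPC in L_C 0.45, DPPC
    in L_E 0.75, DChol 0.25.
    """

    a_HD: float = 0.2
    a_DC: float = 0.45
    a_DL: float = 0.75
    a_c: float = 0.25

    def __post_init__(self) -> None:
        for name in ("a_HD", "a_DC", "a_DL", "a_c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.a_DL > self.a_DC:
            raise ValueError(
                "expanded-phase DPPC area a_DL must exceed condensed-phase a_DC"
            )


@dataclass(frozen=True)
class CompositionModel:
    """Spreading composition and crystal stoichiometry.

    b : DPPC:(HD|PA) mole ratio of the spreading solution.
    n : integer crystal stoichiometry (DPPC per HD/PA in the L_C cocrystal).
    j : DChol mole fraction of all molecules (including DChol itself).
    N : reference HD molecule count; cancels in the area fraction.
    """

    b: float
    n: int = 2
    j: float = 0.0
    N: float = 1.0

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("b must be positive")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be an integer >= 1, got {self.n!r}")
        if not (0.0 <= self.j < 1.0):
            raise ValueError("j must be in [0, 1)")
        if self.b < self.n:
            raise ValueError(
                f"b = {self.b} < n = {self.n}: HD/PA must be the limiting species"
            )


@dataclass(frozen=True)
class AreaFractionObservation:
    """A measured L_C area fraction at spreading ratio b."""

    b: float
    phi: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 1.0):
            raise ValueError("phi must lie strictly in (0, 1)")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def phase_areas(
    m: CompositionModel, areas: MolecularAreas | None = None
) -> tuple[float, float]:
    """(A_B, A_R): condensed and expanded phase areas per reference N (nm^2)."""
    areas = areas or MolecularAreas()
    a_b = m.N * (areas.a_HD + m.n * areas.a_DC)
    a_r = m.N * (m.b - m.n) * areas.a_DL + m.j * (m.b + 1.0) / (1.0 - m.j) * m.N * areas.a_c
    return a_b, a_r


def area_fraction(m: CompositionModel, areas: MolecularAreas | None = None) -> float:
    """L_C area fraction phi = A_B / (A_B + A_R), in (0, 1]."""
    a_b, a_r = phase_areas(m, areas)
    return a_b / (a_b + a_r)


def area_fraction_curve(
    b_grid: np.ndarray, n: int, j: float = 0.0, areas: MolecularAreas | None = None
) -> np.ndarray:
    """phi(b) evaluated on a grid of spreading ratios for a candidate n."""
    return np.array(
        [area_fraction(CompositionModel(b=float(b), n=n, j=j), areas) for b in b_grid]
    )


@dataclass
class StoichiometryFit:
    """Result of an integer-stoichiometry fit to area-fraction data."""

    n_best: int
    sse: dict[int, float]
    excluded: list[int] = field(default_factory=list)
    weighted: bool = False
    tie: bool = False
    observations: list[AreaFractionObservation] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Crystal stoichiometry fit (lever-rule area fractions)",
            f"  observations : {len(self.observations)}",
            f"  weighting    : {'1/sd^2' if self.weighted else 'unweighted'}",
            "  candidate  SSE",
        ]
        for n in sorted(self.sse):
            marker = "  <-- best" if n == self.n_best else ""
            lines.append(f"  n = {n}     {self.sse[n]:.6g}{marker}")
        for n in self.excluded:
            lines.append(f"  n = {n}     excluded (b < n for some observation)")
        if self.tie:
            lines.append("  (tie broken toward smaller n)")
        return "\n".join(lines)


def fit_stoichiometry(
    observations: list[AreaFractionObservation],
    j: float = 0.0,
    areas: MolecularAreas | None = None,
    candidates: tuple[int, ...] = (1, 2, 3),
    weighted: bool = False,
) -> StoichiometryFit:
    """Select the integer stoichiometry n minimising the SSE of phi(b).

    Candidates that violate b >= n for any observation are excluded with
    a warning.  Ties are broken toward smaller n.  With ``weighted``,
    residuals are scaled by 1/sd (observations with sd = 0 fall back to
    unit weight).
    """
    if len(observations) < 2:
        raise ValueError("need at least 2 observations at distinct b")
    if len({o.b for o in observations}) < 2:
        raise ValueError("observations must cover at least 2 distinct b values")
    sse: dict[int, float] = {}
    excluded: list[int] = []
    for n in candidates:
        if any(o.b < n for o in observations):
            warnings.warn(
                f"candidate n={n} excluded: some observation has b < n", stacklevel=2
            )
            excluded.append(n)
            continue
        total = 0.0
        for o in observations:
            pred = area_fraction(CompositionModel(b=o.b, n=n, j=j), areas)
            res = o.phi - pred
            if weighted and o.sd > 0:
                res /= o.sd
            total += res * res
        sse[n] = total
    if not sse:
        raise ValueError("all candidate stoichiometries were excluded")
    best = min(sse, key=lambda n: (sse[n], n))
    tie = sum(1 for v in sse.values() if math.isclose(v, sse[best], rel_tol=1e-12)) > 1
    return StoichiometryFit(
        n_best=best,
        sse=sse,
        excluded=excluded,
        weighted=weighted,
        tie=tie,
        observations=list(observations),
    )
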