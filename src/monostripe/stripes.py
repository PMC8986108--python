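"""Square-to-rectangle (circle-to-stripe) equilibrium branch structure.

As the inverse Bond number lambda/mu^2 drops, a compact (square-like)
domain of fixed area A becomes unstable with respect to elongation into
a rectangle/stripe.  The transition is governed by a transcendental
width equation obtained by minimising the rectangle free energy over
the width w at fixed A.  Scaling lengths by the critical width

    w_c = delta (1 + sqrt(2)) exp(sqrt(2) + lambda/mu^2)  (~ 9.93 delta e^(lambda/mu^2))

collapses the branch diagram onto a single parameter-free curve: a
square branch w_bar = sqrt(A_bar) for A_bar <= 1 and a rectangular
branch for A_bar > 1 that approaches the limiting reduced width

    w_bar -> 2 e^(1 - sqrt(2)) / (1 + sqrt(2)) = 0.5475...

so that large stripes share a universal width w = 2 e delta
exp(lambda/mu^2) ~ 5.5 delta e^(lambda/mu^2) regardless of their
length.  Inverting that relation turns a measured stripe width into an
estimate of lambda/mu^2 — the only route to this ratio at
liquid-condensed/liquid-expanded coexistence, where boundary
fluctuations are too small to analyse.

All lengths in nm unless stated otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .energetics import BondParameters

__all__ = [
    "RectangleDomain",
    "BranchPoint",
    "CriticalGeometry",
    "NoRectangularRootError",
    "rectangle_free_energy",
    "width_equation_residual",
    "critical_geometry",
    "critical_width_numeric",
    "solve_rectangular_branch",
    "square_branch",
    "asymptotic_width",
    "limiting_stripe_width",
    "bond_number_from_width",
    "bifurcation_area",
    "branch_diagram",
    "LIMITING_WIDTH_BAR",
    "CRITICAL_WIDTH_COEFF",
    "EXACT_WIDTH_PREFACTOR",
    "ROUNDED_WIDTH_PREFACTOR",
]

_SQRT2 = math.sqrt(2.0)

#: limiting reduced stripe width, 2 e^(1-sqrt2) / (1+sqrt2) = 0.54752...
LIMITING_WIDTH_BAR = 2.0 * math.exp(1.0 - _SQRT2) / (1.0 + _SQRT2)
#: critical-width coefficient (1+sqrt2) e^sqrt2 = 9.9306...
CRITICAL_WIDTH_COEFF = (1.0 + _SQRT2) * math.exp(_SQRT2)
#: exact limiting-width prefactor 2e = 5.4366...
EXACT_WIDTH_PREFACTOR = 2.0 * math.e
#: conventional rounded prefactor used in width -> Bond-number tables
ROUNDED_WIDTH_PREFACTOR = 5.5
#: constant ln((1+sqrt2) e^(sqrt2-1)) of the scaled width equation
_SCALED_CONST = math.log((1.0 + _SQRT2) * math.exp(_SQRT2 - 1.0))


class NoRectangularRootError(ValueError):
    """Raised when the rectangular branch does not exist (A_bar <= 1)."""


@dataclass(frozen=True)
class RectangleDomain:
    """Rectangle of width ``w`` and length ``l`` (nm), w <= l."""

    w: float
    l: float

    def __post_init__(self) -> None:
        if not (0 < self.w <= self.l):
            raise ValueError(f"need 0 < w <= l, got w={self.w}, l={self.l}")

    @property
    def area(self) -> float:
        return self.w * self.l


@dataclass(frozen=True)
class BranchPoint:
    """A point (A_bar, w_bar) on the scaled solution branch."""

    A_bar: float
    w_bar: float
    branch: str  # "square" | "rectangle"

    def __post_init__(self) -> None:
        if self.A_bar <= 0 or self.w_bar <= 0:
            raise ValueError("A_bar and w_bar must be positive")
        if self.branch not in ("square", "rectangle"):
            raise ValueError(f"unknown branch tag {self.branch!r}")
        if self.branch == "square" and abs(self.w_bar**2 - self.A_bar) > 1e-10:
            raise ValueError("square branch requires w_bar^2 == A_bar")


@dataclass(frozen=True)
class CriticalGeometry:
    """Critical width w_c and area A_c = w_c^2 of the square/rectangle bifurcation."""

    w_c: float

    @property
    def A_c(self) -> float:
        return self.w_c**2


def rectangle_free_energy(d: RectangleDomain, p: BondParameters) -> float:
    """Rectangle free energy F/(2 mu^2), a length.

    F/(2 mu^2) = [c + ln(e^2 delta / A) + ln(w + h)] w
               + [c + ln(e^2 delta / A) + ln(l + h)] l - 2 h

    with c = lambda/mu^2, h = sqrt(w^2 + l^2) and A = w l.  Symmetric
    under (w, l) exchange; its w-derivative at fixed A reproduces
    ``width_equation_residual`` R via d(F/2mu^2)/dw = -R / w^2 (this
    consistency pins the logarithm constant and is asserted in the test
    suite).
    """
    f = _rectangle_energy_raw(d.w, d.l, p.lambda_over_mu2, p.delta)
    if p.absolute:
        f *= 2.0 * p.mu2
    return f


def _rectangle_energy_raw(w: float, l: float, c: float, delta: float) -> float:
    # symmetric in (w, l) by construction
    area = w * l
    h = math.hypot(w, l)
    const = c + math.log(math.e**2 * delta / area)
    return (const + math.log(w + h)) * w + (const + math.log(l + h)) * l - 2.0 * h


def _residual_raw(w: float, area: float, c: float, delta: float) -> float:
    # Eq. holds formally for any w > 0; orientation (w^2 <= A) is enforced
    # by the public wrapper only.
    s = math.hypot(area, w * w)
    t1 = area * math.log((area + s) / (area * w))
    t2 = w * w * math.log((w * w + s) / (area * w))
    t3 = (area - w * w) * math.log(delta * math.exp(1.0 + c))
    return t1 - t2 + t3


def width_equation_residual(w: float, area: float, p: BondParameters) -> float:
    """Residual of the width equation -(w^2 / 2 mu^2) dF/dw = 0 at fixed area.

    R(w, A) = A ln((A + S)/(A w)) - w^2 ln((w^2 + S)/(A w))
              + (A - w^2) ln(delta e^(1 + lambda/mu^2)),   S = sqrt(A^2 + w^4).

    Exactly zero on the square locus w^2 = A for any parameters.  The
    caller must orient the rectangle so that w is the short side.
    """
    if w <= 0 or area <= 0:
        raise ValueError("w and area must be positive")
    if w * w > area * (1.0 + 1e-12):
        raise ValueError(
            f"w={w} is not the short side for area={area}; swap w and l"
        )
    return _residual_raw(w, area, p.lambda_over_mu2, p.delta)


def critical_geometry(p: BondParameters) -> CriticalGeometry:
    """Closed-form critical width w_c = delta (1+sqrt2) e^(sqrt2 + lambda/mu^2)."""
    w_c = p.delta * (1.0 + _SQRT2) * math.exp(_SQRT2 + p.lambda_over_mu2)
    return CriticalGeometry(w_c=w_c)


def critical_width_numeric(p: BondParameters) -> float:
    """Critical width located numerically from the width equation itself.

    The square locus w = sqrt(A) is always a root of the width
    equation; the rectangular root merges with it where the residual
    has a double root, i.e. where dR/dw vanishes at w = sqrt(A).  This
    routine finds that area by bracketed root search (central finite
    differences, no use of the closed form) and returns w = sqrt(A*).
    Independent oracle for ``critical_geometry``.
    """
    c, delta = p.lambda_over_mu2, p.delta

    def dres_at_square(area: float) -> float:
        w = math.sqrt(area)
        h = 1e-6 * w
        return (
            _residual_raw(w + h, area, c, delta)
            - _residual_raw(w - h, area, c, delta)
        ) / (2.0 * h)

    scale = delta * math.exp(c)
    lo, hi = (4.0 * scale) ** 2, (25.0 * scale) ** 2
    area_star = brentq(dres_at_square, lo, hi, rtol=1e-13)
    return math.sqrt(area_star)


def _scaled_residual(w_bar: float, a_bar: float) -> float:
    """Residual of the parameter-free scaled width equation."""
    s = math.hypot(a_bar, w_bar * w_bar)
    t1 = a_bar * math.log((a_bar + s) / (a_bar * w_bar))
    t2 = w_bar * w_bar * math.log((w_bar * w_bar + s) / (a_bar * w_bar))
    return t1 - t2 - (a_bar - w_bar * w_bar) * _SCALED_CONST


def solve_rectangular_branch(
    A_bar: float, w_bar_guess: float | None = None, rtol: float = 1e-12
) -> BranchPoint:
    """Root w_bar < sqrt(A_bar) of the scaled width equation, for A_bar > 1.

    Bracketed search in the gap variable t = 1 - w_bar/sqrt(A_bar): the
    square point t = 0 is always a root, the rectangular root is the
    first interior sign change.  ``w_bar_guess`` (e.g. from a previous
    continuation point) narrows the initial scan near the bifurcation.
    """
    if not A_bar > 1.0:
        raise NoRectangularRootError(
            f"rectangular branch exists only for A_bar > 1, got {A_bar}"
        )
    sq = math.sqrt(A_bar)
    # scan the gap t = 1 - w_bar/sqrt(A_bar): t = 0 is the (always
    # present) square root, the rectangular root is the first interior
    # sign change.  Log spacing in t resolves roots arbitrarily close to
    # the bifurcation.
    lo_w = min(0.3, 0.5 * sq)
    if w_bar_guess is not None:
        lo_w = min(lo_w, 0.8 * w_bar_guess)
    ts = np.geomspace(1e-9, 1.0 - lo_w / sq, 4000)
    ws = sq * (1.0 - ts)  # descending from just below the square point
    vals = np.array([_scaled_residual(float(w), A_bar) for w in ws])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        exact = np.nonzero(vals == 0.0)[0]
        if exact.size:
            return BranchPoint(A_bar=A_bar, w_bar=float(ws[exact[0]]), branch="rectangle")
        raise RuntimeError(
            f"no sign change found for A_bar={A_bar}; residual range "
            f"[{vals.min():.3g}, {vals.max():.3g}]"
        )
    i = idx[0]  # root closest to the square point (ws is descending)
    root = brentq(_scaled_residual, ws[i + 1], ws[i], args=(A_bar,), rtol=rtol)
    return BranchPoint(A_bar=A_bar, w_bar=float(root), branch="rectangle")


def square_branch(A_bar: float) -> BranchPoint:
    """Square branch w_bar = sqrt(A_bar), defined for 0 < A_bar <= 1."""
    if not (0.0 < A_bar <= 1.0):
        raise ValueError(f"square branch requires 0 < A_bar <= 1, got {A_bar}")
    return BranchPoint(A_bar=A_bar, w_bar=math.sqrt(A_bar), branch="square")


#: coefficients of the large-area series for the rectangular branch
_ASYMPTOTIC_COEFFS = (0.547, 0.114, 0.0563, 0.0352, 0.0247)


def asymptotic_width(A_bar: float) -> float:
    """Five-term large-area series for the rectangular-branch width.

    w_bar = 0.547 + 0.114/A_bar + 0.0563/A_bar^2 + 0.0352/A_bar^3
            + 0.0247/A_bar^4, quoted accurate for A_bar >= 1.75.
    """
    if A_bar <= 0:
        raise ValueError("A_bar must be positive")
    if A_bar < 1.75:
        warnings.warn(
            f"asymptotic series is only accurate for A_bar >= 1.75 (got {A_bar})",
            stacklevel=2,
        )
    x = 1.0 / A_bar
    acc = 0.0
    for coef in reversed(_ASYMPTOTIC_COEFFS):
        acc = acc * x + coef
    return acc


def limiting_stripe_width(p: BondParameters) -> float:
    """Limiting stripe width 2 e delta exp(lambda/mu^2) (nm).

    Equals 0.5475 w_c; conventionally rounded to 5.5 delta e^(lambda/mu^2).
    """
    return EXACT_WIDTH_PREFACTOR * p.delta * math.exp(p.lambda_over_mu2)


def bond_number_from_width(
    w: float, delta: float = 1.0, prefactor: float = ROUNDED_WIDTH_PREFACTOR
) -> float:
    """Inverse Bond number lambda/mu^2 = ln(w / (prefactor * delta)).

    ``w`` and ``delta`` in the same length unit.  The default prefactor
    is the conventional 5.5; pass ``EXACT_WIDTH_PREFACTOR`` (= 2e) for
    the exact limiting constant.  Widths at or below prefactor*delta
    would imply lambda/mu^2 <= 0, below the resolution floor of the
    stripe-width method.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if w <= prefactor * delta:
        raise ValueError(
            f"width {w} <= {prefactor}*delta = {prefactor * delta}: the inversion "
            "requires w > prefactor*delta (lambda/mu^2 would be non-positive)"
        )
    return math.log(w / (prefactor * delta))


def bifurcation_area(n_points: int = 12, tol: float = 1e-3) -> float:
    """Scaled area A_bar at which the rectangular branch meets the square branch.

    Traces the rectangular branch toward small A_bar with continuation
    and extrapolates the gap sqrt(A_bar) - w_bar to zero; the merge is
    pitchfork-like so the squared gap closes linearly in A_bar.  Must
    return 1 to within ``tol`` (asserted by the caller's tests, not
    here); independent of all material parameters by construction of the
    scaling.
    """
    a_vals = 1.0 + np.geomspace(1e-5, 0.3, n_points)[::-1]
    gaps = []
    guess = None
    for a in a_vals:
        pt = solve_rectangular_branch(float(a), w_bar_guess=guess)
        guess = pt.w_bar
        gaps.append(math.sqrt(a) - pt.w_bar)
    a_tail = np.asarray(a_vals[-4:])
    g2_tail = np.asarray(gaps[-4:]) ** 2
    slope, intercept = np.polyfit(a_tail, g2_tail, 1)
    a_star = -intercept / slope
    if not (0.5 < a_star < 2.0):
        raise RuntimeError(f"branch tracing failed: extrapolated A_bar = {a_star}")
    return float(a_star)


def branch_diagram(
    A_bar_max: float = 20.0, n: int = 200
):
    """Branch-diagram table (pandas DataFrame).

    Columns: A_bar, w_bar_square (NaN past 1), w_bar_rect (NaN below 1),
    w_bar_asym (NaN below 1).
    """
    import pandas as pd

    a_sq = np.linspace(0.01, 1.0, max(n // 4, 10))
    a_rect = np.geomspace(1.0 + 1e-4, A_bar_max, n)
    rows = []
    for a in a_sq:
        rows.append((float(a), math.sqrt(a), np.nan, np.nan))
    guess = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in a_rect:
            pt = solve_rectangular_branch(float(a), w_bar_guess=guess)
            guess = pt.w_bar
            rows.append((float(a), np.nan, pt.w_bar, asymptotic_width(float(a))))
    return pd.DataFrame(
        rows, columns=["A_bar", "w_bar_square", "w_bar_rect", "w_bar_asym"]
    )
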