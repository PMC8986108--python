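"""Square/rectangle branch structure, width equation and its inversion."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from monostripe.energetics import BondParameters
from monostripe.stripes import (
    CRITICAL_WIDTH_COEFF,
    EXACT_WIDTH_PREFACTOR,
    LIMITING_WIDTH_BAR,
    NoRectangularRootError,
    RectangleDomain,
    asymptotic_width,
    bifurcation_area,
    bond_number_from_width,
    branch_diagram,
    critical_geometry,
    critical_width_numeric,
    limiting_stripe_width,
    rectangle_free_energy,
    solve_rectangular_branch,
    square_branch,
    width_equation_residual,
)


class TestRectangleFreeEnergy:
    def test_symmetric_under_side_exchange(self):
        from monostripe.stripes import _rectangle_energy_raw

        rng = np.random.default_rng(0)
        for _ in range(10):
            w, l = rng.uniform(1.0, 100.0, 2)
            assert _rectangle_energy_raw(w, l, 2.0, 1.0) == pytest.approx(
                _rectangle_energy_raw(l, w, 2.0, 1.0), rel=1e-14
            )

    @pytest.mark.parametrize(
        "c,delta,area,w",
        [(0.0, 1.0, 50.0, 3.0), (2.0, 1.0, 500.0, 10.0), (7.0, 0.5, 1e8, 5e3)],
    )
    def test_derivative_consistency_with_width_equation(self, c, delta, area, w):
        """Central FD of F/(2 mu^2) at fixed area equals -R/w^2.

        This is the authoritative check pinning the free-energy
        logarithm constant to the width equation.
        """
        p = BondParameters(c, delta)

        def f(wv):
            lv = area / wv
            return rectangle_free_energy(RectangleDomain(w=min(wv, lv), l=max(wv, lv)), p)

        h = 1e-6 * w
        fd = (f(w + h) - f(w - h)) / (2.0 * h)
        expected = -width_equation_residual(w, area, p) / w**2
        assert fd == pytest.approx(expected, rel=1e-6)

    def test_constrained_derivative_vanishes_at_square_point(self):
        p = BondParameters(1.5, 1.0)
        area = 400.0
        w = math.sqrt(area)

        def f(wv):
            lv = area / wv
            return rectangle_free_energy(RectangleDomain(w=min(wv, lv), l=max(wv, lv)), p)

        h = 1e-5 * w
        fd = (f(w + h) - f(w - h)) / (2.0 * h)
        assert abs(fd) < 1e-6 * abs(f(w)) / w

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            RectangleDomain(w=-1.0, l=2.0)
        with pytest.raises(ValueError):
            RectangleDomain(w=3.0, l=2.0)  # w must be the short side


class TestWidthEquation:
    @given(
        c=st.floats(0.0, 10.0),
        delta=st.floats(0.5, 2.0),
        area=st.floats(1e-2, 1e8),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_square_locus_is_exact_root(self, c, delta, area):
        """R(sqrt(A), A) = 0 to 1e-12 of the natural scale for any parameters."""
        p = BondParameters(c, delta)
        res = width_equation_residual(math.sqrt(area), area, p)
        scale = max(area * (1.0 + c), 1.0)
        assert abs(res) < 1e-12 * scale

    def test_large_area_root_approaches_two_e(self):
        p = BondParameters(0.0, 1.0)
        root = brentq(
            lambda w: width_equation_residual(w, 1e6, p), 1.0, 20.0, rtol=1e-13
        )
        # finite-area correction at A = 1e6 is ~2e-5 relative
        assert root == pytest.approx(2.0 * math.e, rel=1e-4)

    def test_residual_changes_sign_across_rectangular_root(self):
        p = BondParameters(0.0, 1.0)
        area = 1e4  # well above the critical area ~98.6
        ws = np.geomspace(1.0, math.sqrt(area) * 0.999, 400)
        vals = [width_equation_residual(float(w), area, p) for w in ws]
        assert np.min(np.sign(vals)) < 0 < np.max(np.sign(vals))

    def test_orientation_guard(self):
        p = BondParameters(0.0, 1.0)
        with pytest.raises(ValueError):
            width_equation_residual(11.0, 100.0, p)


class TestCriticalGeometry:
    def test_closed_form_coefficient(self):
        g = critical_geometry(BondParameters(0.0, 1.0))
        assert g.w_c == pytest.approx(CRITICAL_WIDTH_COEFF, rel=1e-14)
        assert g.A_c == pytest.approx(g.w_c**2, rel=1e-14)

    def test_limiting_width_is_0547_of_critical(self):
        # 0.5475 * 9.9306 = 2e: the product of the two reconstructed constants
        assert LIMITING_WIDTH_BAR * CRITICAL_WIDTH_COEFF == pytest.approx(
            2.0 * math.e, rel=1e-12
        )

    def test_exponential_scaling_in_bond_ratio(self):
        w0 = critical_geometry(BondParameters(0.0, 1.0)).w_c
        w1 = critical_geometry(BondParameters(1.0, 1.0)).w_c
        assert w1 / w0 == pytest.approx(math.e, rel=1e-12)

    @pytest.mark.parametrize("c,delta", [(0.0, 1.0), (3.0, 0.7), (6.0, 1.5)])
    def test_numeric_branch_merge_recovers_closed_form(self, c, delta):
        """Locating the double root of the width equation reproduces w_c."""
        p = BondParameters(c, delta)
        assert critical_width_numeric(p) == pytest.approx(
            critical_geometry(p).w_c, rel=1e-6
        )


class TestBranches:
    def test_square_branch_domain_and_values(self):
        assert square_branch(1.0).w_bar == pytest.approx(1.0)
        assert square_branch(0.25).w_bar == pytest.approx(0.5)
        for bad in (0.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                square_branch(bad)

    def test_rectangular_branch_limits(self):
        assert solve_rectangular_branch(1e4).w_bar == pytest.approx(
            LIMITING_WIDTH_BAR, rel=5e-3
        )
        near = solve_rectangular_branch(1.0001)
        assert near.w_bar == pytest.approx(math.sqrt(1.0001), abs=0.02)
        with pytest.raises(NoRectangularRootError):
            solve_rectangular_branch(0.9)

    def test_rectangular_branch_monotone_decreasing(self):
        a_vals = np.geomspace(1.05, 1e4, 40)
        w_vals = [solve_rectangular_branch(float(a)).w_bar for a in a_vals]
        assert np.all(np.diff(w_vals) < 0)
        # width roughly constant past A_bar = 5
        w5 = solve_rectangular_branch(5.0).w_bar
        assert w5 - LIMITING_WIDTH_BAR < 0.03

    def test_asymptotic_series_matches_numeric_branch(self):
        """Five-term series within 2% of the numeric root over [1.75, 1e4]."""
        for a in np.geomspace(1.75, 1e4, 25):
            numeric = solve_rectangular_branch(float(a)).w_bar
            assert abs(asymptotic_width(float(a)) - numeric) / numeric < 0.02

    def test_asymptotic_series_basics(self):
        assert asymptotic_width(1e12) == pytest.approx(0.547, abs=1e-6)
        x = 1.75
        direct = 0.547 + 0.114 / x + 0.0563 / x**2 + 0.0352 / x**3 + 0.0247 / x**4
        assert asymptotic_width(1.75) == pytest.approx(direct, rel=1e-14)
        with pytest.warns(UserWarning):
            asymptotic_width(1.2)

    def test_bifurcation_at_unit_scaled_area(self):
        assert bifurcation_area() == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize(
        "a_bar,c", [(1.5, 0.0), (3.0, 0.0), (10.0, 1.0), (100.0, 3.0), (1e4, 7.0)]
    )
    def test_brute_force_energy_minimum_agrees_with_root(self, a_bar, c):
        """Grid minimisation of the rectangle energy lands on the width-equation root."""
        p = BondParameters(c, 1.0)
        w_c = critical_geometry(p).w_c
        area = a_bar * w_c**2
        w_pred = w_c * solve_rectangular_branch(a_bar).w_bar
        grid = np.geomspace(0.05 * w_pred, math.sqrt(area) * 0.99999, 5000)

        def f(wv):
            lv = area / wv
            return rectangle_free_energy(RectangleDomain(w=min(wv, lv), l=max(wv, lv)), p)

        energies = np.array([f(float(w)) for w in grid])
        w_min = grid[np.argmin(energies)]
        step = grid[1] / grid[0]
        assert w_min / w_pred < step * 1.0001 and w_pred / w_min < step * 1.0001


class TestWidthInversion:
    def test_limiting_width_closed_form(self):
        assert limiting_stripe_width(BondParameters(0.0, 1.0)) == pytest.approx(
            2.0 * math.e, rel=1e-14
        )
        w = limiting_stripe_width(BondParameters(7.0, 1.0))
        assert w == pytest.approx(2.0 * math.e * math.exp(7.0), rel=1e-14)
        assert 5.9e3 < w < 6.05e3  # ~6 um: the 3:1 equilibrium stripe scale

    def test_seven_micron_width_gives_bond_ratio_about_seven(self):
        val = bond_number_from_width(7000.0, 1.0)
        assert val == pytest.approx(math.log(7000.0 / 5.5), rel=1e-14)
        assert round(val) == 7

    def test_four_micron_width_falls_in_transition_band(self):
        val = bond_number_from_width(4000.0, 1.0)
        assert 6.0 < val < 7.0
        assert val == pytest.approx(6.589, abs=1e-3)

    def test_resolution_floor_raises(self):
        assert bond_number_from_width(5.5 + 1e-9, 1.0) >= 0.0
        with pytest.raises(ValueError):
            bond_number_from_width(5.5, 1.0)
        with pytest.raises(ValueError):
            bond_number_from_width(3.0, 1.0)

    @pytest.mark.parametrize("c", [0.5, 3.0, 7.0])
    def test_round_trip_within_prefactor_rounding(self, c):
        """ln(5.5/2e) = 0.0116 bounds the 5.5-vs-2e rounding mismatch."""
        p = BondParameters(c, 1.0)
        w = limiting_stripe_width(p)
        recovered = bond_number_from_width(w, 1.0)  # conventional 5.5 prefactor
        assert abs(recovered - c) <= math.log(5.5 / EXACT_WIDTH_PREFACTOR) + 1e-12
        exact = bond_number_from_width(w, 1.0, prefactor=EXACT_WIDTH_PREFACTOR)
        assert exact == pytest.approx(c, abs=1e-12)


def test_branch_diagram_table():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = branch_diagram(A_bar_max=50.0, n=60)
    rect = df["w_bar_rect"].dropna()
    assert np.all(np.diff(rect.values) < 0)
    sq = df.dropna(subset=["w_bar_square"])
    assert np.allclose(sq["w_bar_square"] ** 2, sq["A_bar"], rtol=1e-12)
    tail = df.dropna(subset=["w_bar_rect", "w_bar_asym"])
    big = tail[tail["A_bar"] >= 1.75]
    rel = np.abs(big["w_bar_asym"] - big["w_bar_rect"]) / big["w_bar_rect"]
    assert rel.max() < 0.02
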