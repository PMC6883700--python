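"""The Buchberger engine: division, S-polynomials, reduced bases, chains.

The reduced lex basis is unique, so the printed bases of the worked
systems are compared coefficient-for-coefficient after monic scaling, and
sympy's groebner acts as an independent CAS oracle on random systems.
"""

from fractions import Fraction

import pytest

from switchscan import (
    LexOrder,
    NotZeroDimensionalError,
    Polynomial,
    buchberger,
    extract_triangular,
    groebner_basis,
    poly_reduce,
    s_polynomial,
    univariate_in,
)
from switchscan.groebner import ResourceGuardError

from conftest import make_poly, random_polynomial, random_system


class TestDivision:
    def test_reduce_by_self_gives_zero(self, wilhelm_equations):
        _, polys, order = wilhelm_equations
        assert poly_reduce(polys[0], [polys[0]], order).is_zero

    def test_member_of_generating_set_reduces_to_zero(self, wilhelm_equations):
        _, polys, order = wilhelm_equations
        assert poly_reduce(polys[1], polys, order).is_zero

    def test_remainder_is_fully_reduced_and_consistent(self, rng):
        order = LexOrder(("x", "y"))
        checked = 0
        while checked < 50:
            variables, basis = random_system(rng, nvars=2, npolys=2)
            p = random_polynomial(rng, variables, max_degree=3)
            r = poly_reduce(p, basis, order)
            # no remainder term divisible by a basis leading term
            for g in basis:
                lm = g.leading_monomial(order)
                for m in r.terms:
                    assert not all(a <= b for a, b in zip(lm, m))
            # division is idempotent on its own remainder
            assert poly_reduce(r, basis, order).terms == r.terms
            # p - r lies in the ideal: certified by reduction to zero
            # modulo a Gröbner basis of that ideal
            try:
                gb = buchberger(basis, order, max_pairs=5000)
            except ResourceGuardError:
                continue
            assert gb.contains(p - r)
            checked += 1


class TestSPolynomial:
    def test_self_pair_cancels(self, wilhelm_equations):
        _, polys, order = wilhelm_equations
        assert s_polynomial(polys[0], polys[0], order).is_zero

    def test_coprime_heads_reduce_to_zero(self):
        xy = ("x", "y")
        order = LexOrder(xy)
        p = make_poly(xy, {(1, 0): 1, (0, 0): -1})  # x - 1
        q = make_poly(xy, {(0, 1): 1, (0, 0): -1})  # y - 1
        s = s_polynomial(p, q, order)
        assert poly_reduce(s, [p, q], order).is_zero

    def test_head_drops_below_lcm(self, rng):
        order = LexOrder(("x", "y"))
        for _ in range(100):
            variables, (p, q) = random_system(rng, nvars=2, npolys=2)
            s = s_polynomial(p, q, order)
            if s.is_zero:
                continue
            lcm = tuple(max(a, b) for a, b in zip(
                p.leading_monomial(order), q.leading_monomial(order)))
            assert order.key(s.leading_monomial(order), variables) < \
                order.key(lcm, variables)

    def test_zero_input_rejected(self):
        xy = ("x", "y")
        with pytest.raises(ValueError):
            s_polynomial(Polynomial.zero(xy),
                         Polynomial.variable(xy, "x"), LexOrder(xy))


class TestBuchberger:
    def test_minimal_bistable_system_basis(self, wilhelm_equations):
        """The two-polynomial steady-state system yields the printed
        basis: univariate x^3 - 8x^2 + 12x and y - x^2/8 (monic form)."""
        _, polys, order = wilhelm_equations
        gb = buchberger(polys, order)
        got = [g.terms for g in gb.polynomials]
        want_g1 = make_poly(("x", "y"),
                            {(3, 0): 1, (2, 0): -8, (1, 0): 12}).terms
        want_g2 = make_poly(("x", "y"),
                            {(0, 1): 1, (2, 0): Fraction(-1, 8)}).terms
        assert got == [want_g1, want_g2]

    def test_linear_system_is_gaussian_elimination(self):
        xy = ("x", "y")
        order = LexOrder(xy)
        f1 = make_poly(xy, {(1, 0): 1, (0, 1): 1, (0, 0): -3})
        f2 = make_poly(xy, {(1, 0): 1, (0, 1): -1, (0, 0): -1})
        gb = buchberger([f1, f2], order)
        assert [g.terms for g in gb.polynomials] == [
            make_poly(xy, {(0, 1): 1, (0, 0): -1}).terms,   # y - 1
            make_poly(xy, {(1, 0): 1, (0, 0): -2}).terms,   # x - 2
        ]

    def test_agrees_with_cas_oracle_on_random_systems(self, rng):
        order = LexOrder(("x", "y"))
        checked = 0
        while checked < 50:
            variables, polys = random_system(rng, nvars=2, npolys=2)
            try:
                groebner_basis(polys, order, backend="both", max_pairs=5000)
            except ResourceGuardError:
                continue
            checked += 1

    def test_every_input_reduces_to_zero_modulo_basis(self, rng):
        order = LexOrder(("x", "y", "z"))
        for _ in range(20):
            variables, polys = random_system(rng, nvars=3, npolys=3,
                                             max_degree=2)
            try:
                gb = buchberger(polys, order, max_pairs=5000)
            except ResourceGuardError:
                continue
            for f in polys:
                assert gb.contains(f)

    def test_deterministic(self, wilhelm_equations):
        _, polys, order = wilhelm_equations
        a = buchberger(polys, order)
        b = buchberger(list(reversed(polys)), order)
        assert [g.terms for g in a.polynomials] == \
            [g.terms for g in b.polynomials]

    def test_resource_guard_trips_loudly(self, wilhelm_equations):
        _, polys, order = wilhelm_equations
        with pytest.raises(ResourceGuardError):
            buchberger(polys, order, max_pairs=0)


class TestTriangularChain:
    def test_unswitchable_output_system_chain(self):
        """The constructed Z/Y system yields the printed three-element
        basis with univariate Y^2 - 19Y + 90."""
        zy = ("Z", "Y")
        f1 = make_poly(zy, {(3, 0): -1, (2, 0): 6, (1, 0): -11, (0, 0): 6})
        f2 = make_poly(zy, {(0, 1): -1, (2, 0): -1, (1, 0): 4, (0, 0): 6})
        gb = buchberger([f1, f2], LexOrder(zy))
        chain = extract_triangular(gb)
        assert chain.univariate.terms == make_poly(
            zy, {(0, 2): 1, (0, 1): -19, (0, 0): 90}).terms
        assert len(gb.polynomials) == 3  # more elements than unknowns
        (var, stage), = chain.stages
        assert var == "Z" and len(stage) == 2

    def test_single_polynomial_chain(self):
        p = make_poly(("x",), {(1,): 1, (0,): -5})
        gb = buchberger([p], LexOrder(("x",)))
        chain = extract_triangular(gb)
        assert chain.univariate.terms == p.terms
        assert chain.stages == []

    def test_positive_dimensional_ideal_is_refused(self):
        xy = ("x", "y")
        p = make_poly(xy, {(1, 1): 1})  # xy = 0: two whole lines
        gb = buchberger([p], LexOrder(xy))
        with pytest.raises(NotZeroDimensionalError):
            extract_triangular(gb)


class TestUnivariateIn:
    def test_reordered_univariate_for_second_output(self, wilhelm_equations):
        """Re-eliminating with y last gives y^3 - 5y^2 + 2.25y (monic form
        of the printed -2.25y + 5y^2 - y^3)."""
        _, polys, _ = wilhelm_equations
        g = univariate_in(polys, "y")
        assert g.terms == make_poly(
            ("x", "y"), {(0, 3): 1, (0, 2): -5, (0, 1): Fraction(9, 4)}).terms

    def test_trivial_univariate(self):
        p = make_poly(("x",), {(1,): 1, (0,): -1})
        assert univariate_in([p], "x").terms == p.terms

    def test_inflow_network_univariate_in_z(self, fixture_reports):
        """The three-species inflow network's cofactor branch has the
        printed cubic 24 - 26Z + 9Z^2 - Z^3 (monic: Z^3 - 9Z^2 + 26Z - 24)."""
        defn, report = fixture_reports["example4"]
        main = next(br for br in report.branches if br.label == "main")
        g1 = main.basis.univariate_element()
        coeffs = g1.univariate_coefficients("Z")
        assert coeffs == [1, -9, 26, -24]


def test_solution_preservation_against_cas(rng, wilhelm_equations):
    """Numeric solutions of F and of its basis agree (same ideal)."""
    import numpy as np
    import sympy as sp

    _, polys, order = wilhelm_equations
    gb = buchberger(polys, order)
    sx, sy = sp.symbols("x y")
    sols_F = sp.solve([p.to_sympy() for p in polys], [sx, sy])
    sols_G = sp.solve([g.to_sympy() for g in gb.polynomials], [sx, sy])
    pts_F = sorted((float(a), float(b)) for a, b in sols_F)
    pts_G = sorted((float(a), float(b)) for a, b in sols_G)
    assert np.allclose(pts_F, pts_G, atol=1e-8)
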