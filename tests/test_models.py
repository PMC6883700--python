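"""Model assembly: mass-action ODEs, conservation elimination,
denominator clearing, exact rationalisation."""

import random
from fractions import Fraction

import pytest
import sympy as sp

from switchscan import (
    ConservationConstraint,
    Polynomial,
    Reaction,
    ReactionNetwork,
    build_system,
    clear_denominators,
    constraint_is_structural,
    eliminate_conserved,
    load_fixture,
    mass_action_odes,
    rationalize,
)
from switchscan.models import UnsupportedModelError, parse_rational_expression

from conftest import make_poly


class TestRationalize:
    @pytest.mark.parametrize("text,expected", [
        ("1.5", Fraction(3, 2)),
        ("8.5", Fraction(17, 2)),
        ("3/2", Fraction(3, 2)),
        ("1.0625e-4", Fraction(17, 160000)),
        (24, Fraction(24)),
    ])
    def test_literal(self, text, expected):
        assert rationalize(text) == expected

    def test_snap_table_maps_printed_rounding_to_exact(self):
        snap = {"0.166": "1/6", "1.667": "5/3"}
        assert rationalize("0.166", snap) == Fraction(1, 6)
        assert rationalize("1.667", snap) == Fraction(5, 3)
        # without snap, strictly literal
        assert rationalize("0.166") == Fraction(166, 1000)

    def test_non_numeric_rejected(self):
        with pytest.raises(ValueError):
            rationalize("k1*2")


class TestMassAction:
    def test_minimal_bistable_network(self):
        """Four reactions with k1=8, k2=k3=1, k4=1.5 assemble into
        dx/dt = 16y - x^2 - xy - 1.5x, dy/dt = x^2 - 8y."""
        system = build_system(load_fixture("wilhelm"))
        xy = system.variables
        assert xy == ("x", "y")
        assert system.rhs_numerators[0].terms == make_poly(
            xy, {(0, 1): 16, (2, 0): -1, (1, 1): -1,
                 (1, 0): Fraction(-3, 2)}).terms
        assert system.rhs_numerators[1].terms == make_poly(
            xy, {(2, 0): 1, (0, 1): -8}).terms
        assert system.is_polynomial

    def test_empty_network(self):
        net = ReactionNetwork(species=["a", "b"], reactions=[])
        system = mass_action_odes(net)
        assert all(num.is_zero for num in system.rhs_numerators)

    def test_random_network_matches_bruteforce_assembly(self, rng):
        """Term-by-term stoichiometric summation oracle."""
        species = ["a", "b", "c"]
        for _ in range(10):
            reactions = []
            for i in range(5):
                reactants = {s: rng.randint(1, 2)
                             for s in rng.sample(species, rng.randint(1, 2))}
                products = {s: rng.randint(0, 2) for s in
                            rng.sample(species, rng.randint(1, 2))}
                products = {s: n for s, n in products.items() if n}
                k = Fraction(rng.randint(1, 9), rng.randint(1, 4))
                reactions.append(Reaction(reactants, products, k, f"r{i}"))
            net = ReactionNetwork(species=list(species), reactions=reactions)
            system = mass_action_odes(net)
            syms = sp.symbols(species)
            lookup = dict(zip(species, syms))
            for s, num in zip(species, system.rhs_numerators):
                expected = sp.Integer(0)
                for r in reactions:
                    rate = sp.Rational(r.rate_constant)
                    for sr, nu in r.reactants.items():
                        rate *= lookup[sr] ** nu
                    net_st = r.products.get(s, 0) - r.reactants.get(s, 0)
                    expected += net_st * rate
                assert sp.simplify(num.to_sympy() - expected) == 0

    def test_undeclared_species_rejected(self):
        net = ReactionNetwork(
            species=["a"],
            reactions=[Reaction({"ghost": 1}, {"a": 1}, 1)])
        with pytest.raises(ValueError, match="undeclared"):
            mass_action_odes(net)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            Reaction({"a": 1}, {}, 0)

    def test_structural_conservation_detected(self):
        # A -> B, B -> A conserves A + B; A -> 2B does not
        net = ReactionNetwork(
            species=["A", "B"],
            reactions=[Reaction({"A": 1}, {"B": 1}, 1),
                       Reaction({"B": 1}, {"A": 1}, 2)])
        system = mass_action_odes(net)
        good = ConservationConstraint({"A": 1, "B": 1}, 5)
        assert constraint_is_structural(system, good)
        net2 = ReactionNetwork(
            species=["A", "B"],
            reactions=[Reaction({"A": 1}, {"B": 2}, 1)])
        assert not constraint_is_structural(mass_action_odes(net2), good)


class TestEliminateConserved:
    def test_enzyme_pool_elimination(self):
        """Substituting x3 = 30 - x2 reduces the Edelstein scheme to
        dx1/dt = 8.5x1 - x1^2 - x1x2 - x2 + 30,
        dx2/dt = -x1x2 + 60 - 2.2x2 exactly."""
        system = build_system(load_fixture("edelstein"))
        v = system.variables
        assert v == ("x1", "x2")
        assert system.rhs_numerators[0].terms == make_poly(
            v, {(1, 0): Fraction(17, 2), (2, 0): -1, (1, 1): -1,
                (0, 1): -1, (0, 0): 30}).terms
        assert system.rhs_numerators[1].terms == make_poly(
            v, {(1, 1): -1, (0, 0): 60, (0, 1): Fraction(-11, 5)}).terms
        # the eliminated enzyme form is recoverable
        full = system.restore_eliminated({"x1": Fraction(1),
                                          "x2": Fraction(75, 4)})
        assert full["x3"] == 30 - Fraction(75, 4)

    def test_constraint_not_touching_system_is_bookkeeping(self):
        xy = ("x", "y")
        system = mass_action_odes(ReactionNetwork(
            species=list(xy),
            reactions=[Reaction({"x": 1}, {"y": 1}, 1)]))
        constraint = ConservationConstraint({"u": 1, "w": 1}, 4,
                                            eliminate="w")
        reduced = eliminate_conserved(system, constraint, "w")
        assert reduced.variables == system.variables
        assert [p.terms for p in reduced.rhs_numerators] == \
            [p.terms for p in system.rhs_numerators]
        assert constraint in reduced.constraints

    def test_victim_absent_from_constraint_rejected(self):
        system = build_system(load_fixture("edelstein"))
        with pytest.raises(ValueError):
            eliminate_conserved(
                system, ConservationConstraint({"x1": 1, "x2": 1}, 1), "zz")

    def test_elimination_preserves_steady_state_set(self):
        """Steady states of the reduced Edelstein system, extended by the
        constraint, satisfy the original DAE residuals."""
        from switchscan import analyze_system

        defn = load_fixture("edelstein")
        system = build_system(defn)
        report = analyze_system(system, order=defn.order,
                                with_switchability=False)
        x1, x2, x3 = sp.symbols("x1 x2 x3")
        k1, k2, k3, k4, k5, k6 = [sp.Rational(str(v)) for v in
                                  ("8.5", 1, 1, 1, 1, "0.2")]
        f1 = k1 * x1 - k2 * x1 ** 2 - k3 * x1 * x2 + k4 * x3
        f2 = k4 * x3 + k5 * x3 - k3 * x1 * x2 - k6 * x2
        g = x2 + x3 - 30
        assert len(report.records) == 3
        for r in report.records:
            point = {x1: r.state.value("x1"), x2: r.state.value("x2"),
                     x3: r.state.value("x3")}
            for expr in (f1, f2, g):
                assert abs(float(expr.subs(point))) < 1e-9


class TestClearDenominators:
    def test_polynomial_passes_through(self):
        sx = sp.Symbol("x")
        system = clear_denominators([sx ** 2 - 1], ["x"])
        assert system.rhs_numerators[0].terms == make_poly(
            ("x",), {(2,): 1, (0,): -1}).terms
        assert system.rhs_denominators[0].total_degree() == 0

    def test_round_trip_on_random_rational_points(self, rng):
        """f/d equals the input expression wherever defined."""
        sx, sy = sp.symbols("x y")
        expr = (sx * sy - 2) / (sx + sp.Rational(1, 3)) + sy / (sy ** 2 + 1)
        system = clear_denominators([expr, sx - sy], ["x", "y"])
        num, den = system.rhs_numerators[0], system.rhs_denominators[0]
        for _ in range(100):
            px = Fraction(rng.randint(-20, 20), rng.randint(1, 7))
            py = Fraction(rng.randint(-20, 20), rng.randint(1, 7))
            dv = den.evaluate({"x": px, "y": py})
            if dv == 0:
                continue
            ours = num.evaluate({"x": px, "y": py}) / dv
            ref = expr.subs({sx: sp.Rational(px.numerator, px.denominator),
                             sy: sp.Rational(py.numerator, py.denominator)})
            if ref.has(sp.zoo) or ref.has(sp.nan):
                continue
            assert ours == Fraction(int(sp.Rational(ref).p),
                                    int(sp.Rational(ref).q))

    def test_akt_numerator_reproduces_printed_cubic(self):
        """Clearing the insulin/AKT denominators and eliminating x2 gives
        the printed basis cubic 0.0505 - 0.5146x1 + 1.4439x1^2 - x1^3
        (coefficients exact to all printed digits)."""
        from switchscan import analyze_system

        defn = load_fixture("akt")
        system = build_system(defn)
        assert not system.is_polynomial
        report = analyze_system(system, order=defn.order)
        cubic = report.switchability["x1"].cubic
        assert float(cubic.b) == pytest.approx(1.4439, abs=5e-5)
        assert float(cubic.c) == pytest.approx(0.5146, abs=5e-5)
        assert float(cubic.d) == pytest.approx(0.0505, abs=5e-5)

    def test_non_rational_expression_rejected(self):
        sx = sp.Symbol("x")
        with pytest.raises(UnsupportedModelError):
            clear_denominators([sp.exp(sx)], ["x"])

    def test_mapk_steady_states_null_the_cleared_numerators(self):
        """The cleared MEK-cycle numerators vanish at the solved states."""
        from switchscan import analyze_system

        defn = load_fixture("mapk")
        system = build_system(defn)
        report = analyze_system(system, order=defn.order,
                                with_switchability=False)
        assert len(report.records) == 3
        for r in report.records:
            point = {v: r.state.value(v) for v in system.variables}
            for num in system.rhs_numerators:
                scale = max(abs(float(c)) for c in num.terms.values())
                assert abs(float(num.evaluate(point))) < 1e-6 * scale


def test_parse_expression_exact_literals():
    expr = parse_rational_expression("x^2 - 1.5*x + 2/3")
    poly = Polynomial.from_sympy(expr, ("x",))
    assert poly.terms == {(2,): Fraction(1), (1,): Fraction(-3, 2),
                          (0,): Fraction(2, 3)}
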