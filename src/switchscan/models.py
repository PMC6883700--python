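"""Exact polynomial ODE models of biochemical reaction networks.

A model enters the pipeline either as a list of mass-action reactions or
as explicit (rational) right-hand sides.  Either way it is normalised into
a :class:`PolynomialODESystem`: per state variable a numerator and a
denominator polynomial with exact rational coefficients, plus the linear
conservation constraints used to eliminate algebraic variables.

All printed decimal parameters are converted to exact rationals
(``1.5 -> 3/2``) before any algebra; per-model "snap tables" map stated
roundings (``0.166 -> 1/6``) to the exact values they stand for.  Snap
tables are explicit, versioned data — never a silent heuristic.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import sympy as sp

from .polys import Polynomial

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ConservationConstraint",
    "PolynomialODESystem",
    "UnsupportedModelError",
    "rationalize",
    "mass_action_odes",
    "eliminate_conserved",
    "clear_denominators",
    "parse_rational_expression",
]


class UnsupportedModelError(ValueError):
    """Right-hand side is not a ratio of polynomials."""


def rationalize(value, snap: Mapping[str, object] | None = None) -> Fraction:
    """Exact rational from a decimal/fraction literal (or number).

    ``snap`` optionally maps printed decimal strings to the exact values
    they abbreviate (e.g. ``{"0.166": "1/6"}``); the mapping is consulted
    before literal conversion, so a snapped model reproduces the intended
    exact coefficients while the default stays strictly literal.
    """
    if snap and isinstance(value, str) and value.strip() in snap:
        return rationalize(snap[value.strip()])
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        # floats only arrive from JSON number literals; exact binary value
        return Fraction(value)
    if isinstance(value, str):
        text = value.strip()
        try:
            if "/" in text:
                return Fraction(text)
            return Fraction(decimal.Decimal(text))
        except (ValueError, ArithmeticError, decimal.InvalidOperation) as exc:
            raise ValueError(f"not a numeric literal: {value!r}") from exc
    raise ValueError(f"not a numeric literal: {value!r}")


@dataclass
class Reaction:
    """A single (mass-action) reaction.

    Zeroth-order inflow is a reaction with an empty reactant map; lumped
    species (a reservoir held at constant concentration) are folded into
    the rate constant and listed among the network's boundary species.
    """

    reactants: dict
    products: dict
    rate_constant: object  # Fraction or parameter-symbol string
    label: str = ""

    def __post_init__(self):
        if any(n <= 0 for n in self.reactants.values()):
            raise ValueError("reactant stoichiometries must be positive")
        if any(n < 0 for n in self.products.values()):
            raise ValueError("product stoichiometries must be nonnegative")
        if isinstance(self.rate_constant, (int, float, Fraction)):
            self.rate_constant = Fraction(self.rate_constant)
            if self.rate_constant <= 0:
                raise ValueError("numeric rate constants must be positive")


@dataclass
class ReactionNetwork:
    species: list
    reactions: list
    parameters: dict = field(default_factory=dict)
    boundary_species: list = field(default_factory=list)
    name: str = ""

    def resolve_rate(self, reaction: Reaction) -> Fraction:
        k = reaction.rate_constant
        if isinstance(k, Fraction):
            return k
        if k not in self.parameters:
            raise ValueError(f"undefined rate constant {k!r}")
        value = rationalize(self.parameters[k])
        if value <= 0:
            raise ValueError(f"rate constant {k!r} must be positive")
        return value


@dataclass
class ConservationConstraint:
    """Linear conservation law  sum_i coeff_i * x_i = total."""

    coefficients: dict
    total: Fraction
    eliminate: str | None = None  # preferred victim variable

    def __post_init__(self):
        self.coefficients = {v: Fraction(c) for v, c in self.coefficients.items()}
        self.total = Fraction(self.total)
        if len(self.coefficients) < 2:
            raise ValueError("a conservation law needs at least two variables")
        if self.total < 0:
            raise ValueError("conserved total must be nonnegative")

    def solve_for(self, victim: str, variables: Sequence[str]) -> Polynomial:
        """The victim expressed as a linear polynomial in the others."""
        if victim not in self.coefficients or self.coefficients[victim] == 0:
            raise ValueError(f"{victim!r} does not appear in the constraint")
        cv = self.coefficients[victim]
        expr = Polynomial.constant(variables, self.total / cv)
        for v, c in self.coefficients.items():
            if v != victim and c != 0:
                expr = expr - Polynomial.variable(variables, v) * (c / cv)
        return expr

    def evaluate_victim(self, victim: str, values: Mapping[str, object]):
        cv = self.coefficients[victim]
        exact = all(isinstance(values.get(v), (int, Fraction))
                    for v in self.coefficients if v != victim)
        total = self.total if exact else float(self.total)
        acc = total
        for v, c in self.coefficients.items():
            if v != victim:
                acc -= (c if exact else float(c)) * values[v]
        return acc / (cv if exact else float(cv))


@dataclass
class PolynomialODESystem:
    """dx_i/dt = f_i(x) / d_i(x) with exact rational polynomial f_i, d_i.

    ``eliminated`` records, per removed conserved variable, the linear
    polynomial that recomputes it from the remaining state — used later to
    restore full states and to reject steady states whose eliminated
    component would be negative.
    """

    variables: tuple
    rhs_numerators: list
    rhs_denominators: list
    parameters: dict = field(default_factory=dict)
    constraints: list = field(default_factory=list)
    eliminated: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        self.variables = tuple(self.variables)
        if len(self.rhs_numerators) != len(self.variables):
            raise ValueError("one right-hand side per variable required")
        if not self.rhs_denominators:
            one = Polynomial.constant(self.variables, 1)
            self.rhs_denominators = [one] * len(self.variables)
        if any(d.is_zero for d in self.rhs_denominators):
            raise ValueError("a rhs denominator is the zero polynomial")

    @property
    def is_polynomial(self) -> bool:
        return all(d.total_degree() == 0 for d in self.rhs_denominators)

    def steady_state_equations(self) -> list:
        """The numerator polynomials f_i whose common zeros (with d_i != 0)
        are the steady states."""
        return list(self.rhs_numerators)

    def rhs_value(self, point: Mapping[str, float]) -> list:
        out = []
        for num, den in zip(self.rhs_numerators, self.rhs_denominators):
            d = den.evaluate(point)
            if d == 0:
                raise ZeroDivisionError("rhs denominator vanishes at point")
            out.append(num.evaluate(point) / d)
        return out

    def restore_eliminated(self, values: dict) -> dict:
        """Extend a state over ``variables`` by the eliminated conserved
        variables."""
        full = dict(values)
        for var, expr in self.eliminated.items():
            full[var] = expr.evaluate(values)
        return full


def constraint_is_structural(system: PolynomialODESystem,
                             constraint: ConservationConstraint) -> bool:
    """True when the stoichiometry itself conserves the combination:
    the symbolic sum  sum_i coeff_i * f_i/d_i  is identically zero.

    Only meaningful before elimination; a declared constraint failing this
    check is a modelling assumption, not a structural conservation law.
    """
    variables = system.variables
    acc_num = Polynomial.zero(variables)
    acc_den = Polynomial.constant(variables, 1)
    for v, c in constraint.coefficients.items():
        if v not in variables:
            continue
        i = variables.index(v)
        num = system.rhs_numerators[i] * c
        den = system.rhs_denominators[i]
        acc_num = acc_num * den + num * acc_den
        acc_den = acc_den * den
    return acc_num.is_zero


def mass_action_odes(network: ReactionNetwork) -> PolynomialODESystem:
    """Assemble mass-action ODEs: for species s,
    ds/dt = sum_r (net stoichiometry of s in r) * k_r * prod [reactant]^nu.

    Boundary (lumped/fixed) species contribute no ODE and no concentration
    factor — their constant levels are already folded into the rate
    constants.
    """
    dynamic = [s for s in network.species if s not in network.boundary_species]
    variables = tuple(dynamic)
    boundary = set(network.boundary_species)
    declared = set(network.species) | boundary
    rhs = {s: Polynomial.zero(variables) for s in dynamic}
    for reaction in network.reactions:
        for s in list(reaction.reactants) + list(reaction.products):
            if s not in declared:
                raise ValueError(f"undeclared species {s!r} in reaction "
                                 f"{reaction.label or reaction!r}")
        k = network.resolve_rate(reaction)
        rate = Polynomial.constant(variables, k)
        for s, nu in reaction.reactants.items():
            if s in boundary:
                continue
            rate = rate * Polynomial.variable(variables, s) ** nu
        for s in dynamic:
            net = reaction.products.get(s, 0) - reaction.reactants.get(s, 0)
            if net:
                rhs[s] = rhs[s] + rate * net
    return PolynomialODESystem(
        variables=variables,
        rhs_numerators=[rhs[s] for s in dynamic],
        rhs_denominators=[Polynomial.constant(variables, 1)] * len(dynamic),
        parameters=dict(network.parameters),
        name=network.name,
    )


def eliminate_conserved(system: PolynomialODESystem,
                        constraint: ConservationConstraint,
                        victim: str | None = None) -> PolynomialODESystem:
    """Substitute a conserved variable away using a linear constraint.

    The victim (by default the constraint's designated variable, else the
    participating variable of largest index in the system's ordering) is
    replaced by its linear expression in the remaining variables; its ODE,
    if any, is dropped.  The constraint is recorded so the eliminated
    component can be restored and checked for nonnegativity afterwards.
    """
    if victim is None:
        victim = constraint.eliminate
    if victim is None:
        participating = [v for v in system.variables
                         if constraint.coefficients.get(v, 0) != 0]
        if not participating:
            raise ValueError("constraint involves no system variable")
        victim = participating[-1]
    if constraint.coefficients.get(victim, 0) == 0:
        raise ValueError(f"victim {victim!r} absent from the constraint")
    if victim not in system.variables:
        # bookkeeping only: the system never mentioned the victim
        out = PolynomialODESystem(
            system.variables, list(system.rhs_numerators),
            list(system.rhs_denominators), dict(system.parameters),
            system.constraints + [constraint], dict(system.eliminated),
            system.name)
        return out

    replacement = constraint.solve_for(victim, system.variables)
    keep = [v for v in system.variables if v != victim]
    nums, dens = [], []
    for v, num, den in zip(system.variables, system.rhs_numerators,
                           system.rhs_denominators):
        if v == victim:
            continue
        nums.append(num.compose(victim, replacement).drop_variables([victim]))
        dens.append(den.compose(victim, replacement).drop_variables([victim]))
    eliminated = {k: (e.compose(victim, replacement).drop_variables([victim])
                      if victim in e.variables else e)
                  for k, e in system.eliminated.items()}
    eliminated[victim] = replacement.drop_variables([victim])
    return PolynomialODESystem(
        variables=tuple(keep),
        rhs_numerators=nums,
        rhs_denominators=dens,
        parameters=dict(system.parameters),
        constraints=system.constraints + [constraint],
        eliminated=eliminated,
        name=system.name,
    )


# --------------------------------------------------------------------------
# expression parsing and denominator clearing (sympy does the rational
# function normalisation; results come back as exact Polynomial pairs)
# --------------------------------------------------------------------------

def parse_rational_expression(text: str, snap: Mapping[str, object] | None = None
                              ) -> sp.Expr:
    """Parse ``+ - * / ^`` expressions with exact rational literals.

    Decimal literals become exact Rationals; snap-table entries are applied
    at the literal level before conversion.
    """
    import re

    from sympy.parsing.sympy_parser import (
        convert_xor, parse_expr, rationalize, standard_transformations)

    # bind every identifier to a plain Symbol so names like beta, E2 or S
    # never resolve to sympy builtins
    local = {name: sp.Symbol(name)
             for name in set(re.findall(r"[A-Za-z_][A-Za-z_0-9]*", text))}
    expr = parse_expr(
        text, local_dict=local, evaluate=False,
        transformations=standard_transformations + (convert_xor, rationalize))
    if snap:
        subs = {}
        for printed, exact in snap.items():
            p = sp.Rational(str(Fraction(decimal.Decimal(printed))))
            e = rationalize_value(exact)
            subs[p] = sp.Rational(e.numerator, e.denominator)
        expr = expr.subs(subs)
    return sp.sympify(expr)


def rationalize_value(value) -> Fraction:
    return rationalize(value)


def clear_denominators(exprs: Sequence[sp.Expr], variables: Sequence[str],
                       name: str = "") -> PolynomialODESystem:
    """Normalise rational right-hand sides into numerator/denominator
    polynomial pairs with no common polynomial factor.

    Steady-state analysis then works on ``f_i = 0`` with the side condition
    ``d_i != 0`` checked during admissibility filtering.
    """
    syms = sp.symbols(tuple(variables)) if variables else ()
    nums, dens = [], []
    for expr in exprs:
        expr = sp.nsimplify(sp.sympify(expr), rational=True)
        if expr.free_symbols - set(syms):
            raise UnsupportedModelError(
                f"expression contains unknown symbols: {expr}")
        if not expr.is_rational_function(*syms):
            raise UnsupportedModelError(
                f"right-hand side is not a rational function: {expr}")
        num, den = sp.fraction(sp.cancel(sp.together(expr)))
        nums.append(Polynomial.from_sympy(num, variables))
        dens.append(Polynomial.from_sympy(den, variables))
    return PolynomialODESystem(tuple(variables), nums, dens, name=name)
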