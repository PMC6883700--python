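"""Solving the triangular chain and filtering admissible steady states.

The univariate basis element is solved by exact real-root isolation
(square-free factorisation with Sturm-sequence counting, as provided by
sympy's certified ``real_roots``); rational roots stay exact Fractions,
irrational ones are refined to double precision.  Each root is then
extended through the chain: every later basis element that involves only
solved variables plus the next one contributes a candidate equation, the
candidates' root sets are intersected, and the extension is accepted only
if its residual vanishes on *every* chain element.

Admissibility then enforces the biology: components real, nonnegative and
pairwise distinct, rate-law denominators nonzero, and eliminated conserved
species (recomputed from the constraints) nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy as sp

from .groebner import TriangularChain
from .models import PolynomialODESystem
from .polys import Polynomial

DISTINCT_TOL = 1e-8      # relative gap below which states count as equal
NEGATIVE_SLACK = 1e-9    # how far below zero a component may numerically sit
IMAG_TOL = 1e-9          # |Im| < IMAG_TOL * (1 + |Re|) counts as real
RESIDUAL_TOL = 1e-8


@dataclass
class SteadyState:
    """One steady state; values may mix exact Fractions and floats."""

    values: dict
    multiplicity: int = 1
    admissible: bool = True
    reasons: list = field(default_factory=list)
    branch: str = ""

    def value(self, var: str) -> float:
        return float(self.values[var])

    def as_floats(self) -> dict:
        return {v: float(x) for v, x in self.values.items()}

    def reject(self, reason: str):
        self.admissible = False
        if reason not in self.reasons:
            self.reasons.append(reason)


def _poly_to_sympy_univariate(coeffs, x):
    expr = sp.Integer(0)
    n = len(coeffs) - 1
    for i, c in enumerate(coeffs):
        expr += sp.Rational(c.numerator, c.denominator) * x ** (n - i)
    return sp.Poly(expr, x)


def real_roots(p: Polynomial, tol: float = 1e-12, var: str | None = None):
    """All real roots of a univariate polynomial with multiplicities.

    Exact isolation on the rational coefficients; rational roots are
    returned as exact ``Fraction``, irrational ones as floats accurate to
    well below ``tol``.  Sorted ascending.
    """
    if p.is_zero:
        raise ValueError("zero polynomial has every number as a root")
    used = p.used_variables()
    if not used:
        return []
    coeffs = p.univariate_coefficients(var)
    x = sp.Dummy("x")
    roots = _poly_to_sympy_univariate(coeffs, x).real_roots()
    out = []
    for r in roots:
        if r.is_rational:
            val = Fraction(int(r.p), int(r.q))
        else:
            val = float(r.evalf(25))
        if out and _close(out[-1][0], val, tol):
            out[-1] = (out[-1][0], out[-1][1] + 1)
        else:
            out.append((val, 1))
    return out


def _close(a, b, tol):
    if isinstance(a, Fraction) and isinstance(b, Fraction):
        return a == b
    return abs(float(a) - float(b)) <= tol * (1.0 + abs(float(a)))


def _float_roots(coeffs, tol=1e-9):
    """Real roots of a float-coefficient univariate polynomial."""
    arr = np.array([float(c) for c in coeffs], dtype=float)
    arr = np.trim_zeros(arr, "f")
    if arr.size <= 1:
        return []
    rts = np.roots(arr)
    scale = max(1.0, float(np.max(np.abs(rts))) if rts.size else 1.0)
    return sorted(float(r.real) for r in rts
                  if abs(r.imag) <= IMAG_TOL * scale * 1e3)


def _solve_stage(poly: Polynomial, assignment: dict, var: str, tol: float):
    """Roots for ``var`` of one chain element under a partial assignment.

    Returns ``None`` when the element degenerates to the zero polynomial
    (no information) and ``[]`` when it is a nonzero constant
    (inconsistent branch).
    """
    exact = all(isinstance(v, (int, Fraction)) for v in assignment.values())
    reduced = poly.partial_eval(assignment)
    if var not in reduced.used_variables():
        const = reduced.evaluate({v: 0 for v in reduced.variables})
        if abs(float(const)) <= tol:
            return None
        return []
    coeffs = reduced.univariate_coefficients(var)
    if exact:
        sub = Polynomial((var,), {(len(coeffs) - 1 - i,): c
                                  for i, c in enumerate(coeffs) if c != 0})
        return [r for r, _ in real_roots(sub, var=var)]
    return _float_roots(coeffs, tol)


def back_substitute(chain: TriangularChain, tol: float = 1e-9,
                    branch: str = "") -> list:
    """Extend every univariate root through the triangular chain.

    Nonlinear stages enumerate all real branches; when several chain
    elements constrain the same new variable their root sets are
    intersected, and every completed assignment is verified against every
    chain element (residual < tol).  An inconsistent partial root is
    dropped, not fatal: a reduced basis can carry more elements than
    variables and not every univariate root extends.
    """
    var0 = chain.order.elimination_variable
    partials = []
    for root, mult in real_roots(chain.univariate, var=var0):
        partials.append(({var0: root}, mult))
    for var, polys in chain.stages:
        extended = []
        for assignment, mult in partials:
            candidate_sets = []
            for g in polys:
                roots = _solve_stage(g, assignment, var, tol)
                if roots is None:
                    continue
                candidate_sets.append(roots)
            if not candidate_sets:
                continue  # chain gives no finite constraint: flag by dropping
            merged = candidate_sets[0]
            for other in candidate_sets[1:]:
                merged = [r for r in merged
                          if any(_close(r, s, tol) for s in other)]
            for r in merged:
                new = dict(assignment)
                new[var] = r
                extended.append((new, mult))
        partials = extended
    # final consistency: residual on every chain element
    states = []
    for assignment, mult in partials:
        ok = True
        for g in chain.all_polynomials():
            scale = 1.0 + max(abs(float(c)) for c in g.terms.values())
            point = {v: assignment.get(v, 0) for v in g.variables}
            if abs(float(g.evaluate(point))) > tol * scale * 1e3:
                ok = False
                break
        if ok:
            states.append(SteadyState(dict(assignment), multiplicity=mult,
                                      branch=branch))
    return states


def admissible_filter(states: list, system: PolynomialODESystem,
                      tol: float = DISTINCT_TOL) -> list:
    """Keep real, nonnegative, pairwise-distinct states with nonvanishing
    rate-law denominators and nonnegative eliminated conserved species.

    Rejected states are returned too (callers may report them); the
    admissible ones carry ``admissible=True``.
    """
    for st in states:
        floats = st.as_floats()
        for v, x in floats.items():
            if x < -NEGATIVE_SLACK * (1.0 + abs(x)):
                st.reject(f"negative component {v}")
        for den in system.rhs_denominators:
            point = {v: floats.get(v, 0.0) for v in den.variables}
            if abs(float(den.evaluate(point))) <= tol:
                st.reject("denominator vanishes")
        full = system.restore_eliminated(st.values)
        for v, x in full.items():
            if v not in st.values:
                st.values[v] = x
                if float(x) < -NEGATIVE_SLACK * (1 + abs(float(x))):
                    st.reject(f"eliminated species {v} negative")
    # pairwise distinctness among the surviving states
    kept = [s for s in states if s.admissible]
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i], kept[j]
            gap = max(abs(a.value(v) - b.value(v)) for v in system.variables)
            scale = 1.0 + max(abs(a.value(v)) for v in system.variables)
            if gap <= tol * scale:
                b.reject("duplicate state")
    return [s for s in states if s.admissible]


def residuals(system: PolynomialODESystem, state: SteadyState) -> list:
    """Steady-state residuals |f_i| at a state, on the original system."""
    floats = state.as_floats()
    out = []
    for num in system.rhs_numerators:
        point = {v: floats.get(v, 0.0) for v in num.variables}
        out.append(abs(float(num.evaluate(point))))
    return out
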