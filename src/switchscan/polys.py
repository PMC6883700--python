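"""Exact multivariate polynomial arithmetic over the rationals.

Every quantity that enters the Gröbner-basis pipeline is carried as a
:class:`Polynomial` with :class:`fractions.Fraction` coefficients.  Exact
arithmetic is not a luxury here: reduced lexicographic bases are unique
only over an exact field, and the integer-coefficient bases this package
reproduces (e.g. ``x^3 - 8x^2 + 12x``) fall out exactly only in rational
arithmetic.

Monomials are exponent tuples aligned to a fixed variable tuple; a
:class:`LexOrder` ranks the variables (highest priority first) and induces
the lexicographic order on monomials.  By convention the *elimination*
variable — the one whose univariate basis element we are after — is ranked
last.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

import sympy as sp

Scalar = Union[int, Fraction]
Monomial = tuple  # exponent tuple aligned to Polynomial.variables


@dataclass(frozen=True)
class LexOrder:
    """Lexicographic monomial order given by a variable ranking.

    ``ranking`` lists variables highest-priority first; the univariate
    basis polynomial of a zero-dimensional lex basis lives in the last
    (lowest-ranked) variable.
    """

    ranking: tuple

    def __init__(self, ranking: Sequence[str]):
        object.__setattr__(self, "ranking", tuple(ranking))
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError("variable ranking contains duplicates")

    @property
    def elimination_variable(self) -> str:
        return self.ranking[-1]

    def key(self, monomial: Monomial, variables: Sequence[str]):
        """Sort key: exponents permuted into ranking order."""
        idx = {v: i for i, v in enumerate(variables)}
        return tuple(monomial[idx[v]] for v in self.ranking)


def lex_compare(m1: Monomial, m2: Monomial, order: LexOrder,
                variables: Sequence[str]) -> int:
    """Compare two aligned exponent tuples under ``order``.

    Returns -1, 0 or 1.  The first differing exponent along the ranking
    decides, which makes the relation a total order.
    """
    if len(m1) != len(m2) or len(m1) != len(variables):
        raise ValueError("exponent tuples not aligned to the variable list")
    k1, k2 = order.key(m1, variables), order.key(m2, variables)
    return (k1 > k2) - (k1 < k2)


def monomial_lcm(m1: Monomial, m2: Monomial) -> Monomial:
    return tuple(max(a, b) for a, b in zip(m1, m2))


def monomial_divides(m1: Monomial, m2: Monomial) -> bool:
    """True when m1 divides m2 (componentwise <=)."""
    return all(a <= b for a, b in zip(m1, m2))


def monomial_div(m1: Monomial, m2: Monomial) -> Monomial:
    return tuple(a - b for a, b in zip(m1, m2))


def monomial_mul(m1: Monomial, m2: Monomial) -> Monomial:
    return tuple(a + b for a, b in zip(m1, m2))


class Polynomial:
    """Multivariate polynomial with exact rational coefficients.

    ``variables`` is an ordered tuple of names; ``terms`` maps exponent
    tuples (aligned to ``variables``) to nonzero ``Fraction`` coefficients.
    """

    __slots__ = ("variables", "terms")

    def __init__(self, variables: Sequence[str],
                 terms: Mapping[Monomial, Scalar] | None = None):
        self.variables = tuple(variables)
        clean = {}
        if terms:
            n = len(self.variables)
            for mono, coeff in terms.items():
                if len(mono) != n:
                    raise ValueError("monomial not aligned to variables")
                c = Fraction(coeff)
                if c != 0:
                    mono = tuple(int(e) for e in mono)
                    clean[mono] = clean.get(mono, Fraction(0)) + c
        self.terms = {m: c for m, c in clean.items() if c != 0}

    # ---------------------------------------------------------------- basic

    @classmethod
    def zero(cls, variables: Sequence[str]) -> "Polynomial":
        return cls(variables, {})

    @classmethod
    def constant(cls, variables: Sequence[str], value: Scalar) -> "Polynomial":
        return cls(variables, {(0,) * len(variables): Fraction(value)})

    @classmethod
    def variable(cls, variables: Sequence[str], name: str) -> "Polynomial":
        mono = tuple(1 if v == name else 0 for v in variables)
        if sum(mono) != 1:
            raise ValueError(f"unknown variable {name!r}")
        return cls(variables, {mono: Fraction(1)})

    @property
    def is_zero(self) -> bool:
        return not self.terms

    def __bool__(self):
        return bool(self.terms)

    def __eq__(self, other):
        if isinstance(other, Polynomial):
            return self.variables == other.variables and self.terms == other.terms
        if isinstance(other, (int, Fraction)):
            return self == Polynomial.constant(self.variables, other)
        return NotImplemented

    def __hash__(self):
        return hash((self.variables, frozenset(self.terms.items())))

    def used_variables(self) -> set:
        used = set()
        for mono in self.terms:
            for v, e in zip(self.variables, mono):
                if e:
                    used.add(v)
        return used

    def total_degree(self) -> int:
        return max((sum(m) for m in self.terms), default=-1)

    def degree_in(self, var: str) -> int:
        i = self.variables.index(var)
        return max((m[i] for m in self.terms), default=-1)

    # ----------------------------------------------------------- arithmetic

    def _coerce(self, other) -> "Polynomial":
        if isinstance(other, Polynomial):
            if other.variables != self.variables:
                raise ValueError("polynomials over different variable tuples")
            return other
        return Polynomial.constant(self.variables, other)

    def __add__(self, other):
        other = self._coerce(other)
        terms = dict(self.terms)
        for m, c in other.terms.items():
            terms[m] = terms.get(m, Fraction(0)) + c
        return Polynomial(self.variables, terms)

    __radd__ = __add__

    def __neg__(self):
        return Polynomial(self.variables, {m: -c for m, c in self.terms.items()})

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        if isinstance(other, (int, Fraction)):
            c0 = Fraction(other)
            return Polynomial(self.variables,
                              {m: c * c0 for m, c in self.terms.items()})
        other = self._coerce(other)
        terms: dict = {}
        for m1, c1 in self.terms.items():
            for m2, c2 in other.terms.items():
                m = monomial_mul(m1, m2)
                terms[m] = terms.get(m, Fraction(0)) + c1 * c2
        return Polynomial(self.variables, terms)

    __rmul__ = __mul__

    def __pow__(self, n: int):
        if n < 0:
            raise ValueError("negative exponent")
        result = Polynomial.constant(self.variables, 1)
        base = self
        while n:
            if n & 1:
                result = result * base
            base = base * base
            n >>= 1
        return result

    def scale(self, c: Scalar) -> "Polynomial":
        return self * Fraction(c)

    # --------------------------------------------------------- order-aware

    def leading_monomial(self, order: LexOrder) -> Monomial:
        if self.is_zero:
            raise ValueError("zero polynomial has no leading monomial")
        return max(self.terms, key=lambda m: order.key(m, self.variables))

    def leading_coefficient(self, order: LexOrder) -> Fraction:
        return self.terms[self.leading_monomial(order)]

    def monic(self, order: LexOrder) -> "Polynomial":
        lc = self.leading_coefficient(order)
        return self * (Fraction(1) / lc)

    def sorted_terms(self, order: LexOrder):
        return sorted(self.terms.items(),
                      key=lambda it: order.key(it[0], self.variables),
                      reverse=True)

    # -------------------------------------------------------- substitution

    def partial_eval(self, assignment: Mapping[str, object]) -> "Polynomial":
        """Substitute numeric values for a subset of the variables.

        Values may be exact (``Fraction``/int) or floats; float input
        degrades the affected coefficients to float (stored as Fractions of
        the exact binary float, so downstream exact paths remain usable).
        """
        idx = [self.variables.index(v) for v in assignment]
        vals = [assignment[self.variables[i]] for i in idx]
        vals = [v if isinstance(v, Fraction) else Fraction(v) for v in vals]
        keep = [i for i in range(len(self.variables)) if i not in idx]
        new_vars = tuple(self.variables[i] for i in keep)
        terms: dict = {}
        for mono, coeff in self.terms.items():
            c = coeff
            for i, v in zip(idx, vals):
                c *= v ** mono[i]
            m = tuple(mono[i] for i in keep)
            terms[m] = terms.get(m, Fraction(0)) + c
        return Polynomial(new_vars, terms)

    def compose(self, var: str, replacement: "Polynomial") -> "Polynomial":
        """Substitute a polynomial for one variable (same variable tuple)."""
        if replacement.variables != self.variables:
            raise ValueError("replacement over different variable tuple")
        i = self.variables.index(var)
        result = Polynomial.zero(self.variables)
        for mono, coeff in self.terms.items():
            rest = list(mono)
            e = rest[i]
            rest[i] = 0
            term = Polynomial(self.variables, {tuple(rest): coeff})
            result = result + term * (replacement ** e)
        return result

    def drop_variables(self, names: Iterable[str]) -> "Polynomial":
        names = set(names)
        if names & self.used_variables():
            raise ValueError("cannot drop variables still in use")
        keep = [i for i, v in enumerate(self.variables) if v not in names]
        return Polynomial(tuple(self.variables[i] for i in keep),
                          {tuple(m[i] for i in keep): c
                           for m, c in self.terms.items()})

    def with_variables(self, variables: Sequence[str]) -> "Polynomial":
        """Re-embed into a (super)set of variables."""
        variables = tuple(variables)
        pos = {v: i for i, v in enumerate(variables)}
        n = len(variables)
        terms = {}
        for mono, coeff in self.terms.items():
            m = [0] * n
            for v, e in zip(self.variables, mono):
                if e:
                    if v not in pos:
                        raise ValueError(f"variable {v!r} missing from target")
                    m[pos[v]] = e
            terms[tuple(m)] = coeff
        return Polynomial(variables, terms)

    def evaluate(self, point: Mapping[str, object]):
        """Evaluate at a full numeric point; returns Fraction or float."""
        exact = all(isinstance(point[v], (int, Fraction)) for v in self.variables)
        total = Fraction(0) if exact else 0.0
        for mono, coeff in self.terms.items():
            term = coeff if exact else float(coeff)
            for v, e in zip(self.variables, mono):
                if e:
                    term *= point[v] ** e if exact else float(point[v]) ** e
            total += term
        return total

    def diff(self, var: str) -> "Polynomial":
        i = self.variables.index(var)
        terms = {}
        for mono, coeff in self.terms.items():
            e = mono[i]
            if e:
                m = list(mono)
                m[i] = e - 1
                m = tuple(m)
                terms[m] = terms.get(m, Fraction(0)) + coeff * e
        return Polynomial(self.variables, terms)

    # --------------------------------------------------------- univariate

    def univariate_coefficients(self, var: str | None = None) -> list:
        """Dense coefficient list [a_n, ..., a_0] of a univariate polynomial."""
        used = self.used_variables()
        if len(used) > 1:
            raise ValueError("polynomial is not univariate")
        if var is None:
            var = next(iter(used)) if used else self.variables[0]
        i = self.variables.index(var)
        deg = self.degree_in(var)
        if deg < 0:
            return [Fraction(0)]
        coeffs = [Fraction(0)] * (deg + 1)
        for mono, coeff in self.terms.items():
            coeffs[deg - mono[i]] += coeff
        return coeffs

    # -------------------------------------------------------------- sympy

    def to_sympy(self) -> sp.Expr:
        syms = sp.symbols(self.variables) if self.variables else ()
        expr = sp.Integer(0)
        for mono, coeff in self.terms.items():
            term = sp.Rational(coeff.numerator, coeff.denominator)
            for s, e in zip(syms, mono):
                if e:
                    term *= s ** e
            expr += term
        return expr

    @classmethod
    def from_sympy(cls, expr: sp.Expr, variables: Sequence[str]) -> "Polynomial":
        variables = tuple(variables)
        expr = sp.nsimplify(sp.expand(expr), rational=True)
        if not variables:
            return cls((), {(): Fraction(sp.Rational(expr))})
        syms = sp.symbols(variables)
        poly = sp.Poly(expr, *syms, domain="QQ")
        terms = {}
        for mono, coeff in poly.terms():
            q = sp.Rational(coeff)
            terms[tuple(int(e) for e in mono)] = Fraction(int(q.p), int(q.q))
        return cls(variables, terms)

    # -------------------------------------------------------------- repr

    def __repr__(self):
        if self.is_zero:
            return "Polynomial(0)"
        parts = []
        for mono, coeff in sorted(self.terms.items(), reverse=True):
            factors = [str(coeff)] if abs(coeff) != 1 or not any(mono) else (
                ["-"] if coeff == -1 else [])
            for v, e in zip(self.variables, mono):
                if e == 1:
                    factors.append(v)
                elif e > 1:
                    factors.append(f"{v}^{e}")
            part = "*".join(f for f in factors if f != "-")
            if factors and factors[0] == "-":
                part = "-" + part
            parts.append(part or str(coeff))
        return " + ".join(parts).replace("+ -", "- ")
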