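"""Reduced lexicographic Gröbner bases via Buchberger's algorithm.

The basis computation is this package's own implementation over exact
rationals: multivariate division, S-polynomials, Buchberger completion with
the normal (smallest-lcm) selection strategy and the coprime-leading-term
criterion, followed by inter-reduction and monic normalisation.  The
reduced basis is unique for a fixed lex order, which is what makes the
printed bases of small reaction networks reproducible coefficient by
coefficient.

An optional sympy backend computes the same reduced basis through
``sympy.groebner`` and serves as an independent cross-check (``backend
="both"`` asserts equality term by term).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import sympy as sp

from .polys import (
    LexOrder,
    Polynomial,
    monomial_div,
    monomial_divides,
    monomial_lcm,
    monomial_mul,
)


class GroebnerError(Exception):
    pass


class ResourceGuardError(GroebnerError):
    """Raised when the S-pair queue exceeds the configured cap."""


class NoUnivariateError(GroebnerError):
    """No basis element is univariate in the designated variable."""


class NotZeroDimensionalError(GroebnerError):
    """The ideal has infinitely many solutions; no triangular chain."""


def poly_reduce(p: Polynomial, basis: Sequence[Polynomial],
                order: LexOrder) -> Polynomial:
    """Remainder of multivariate division of ``p`` by ``basis``.

    No term of the remainder is divisible by any basis leading term, and
    ``p - remainder`` lies in the ideal generated by ``basis``.  Terminates
    because each step strictly decreases the leading monomial considered.
    """
    if any(g.is_zero for g in basis):
        raise ValueError("zero polynomial in division basis")
    variables = p.variables
    lts = [(g.leading_monomial(order), g.leading_coefficient(order), g)
           for g in basis]
    remainder: dict = {}
    work = dict(p.terms)
    while work:
        mono = max(work, key=lambda m: order.key(m, variables))
        coeff = work.pop(mono)
        for lm, lc, g in lts:
            if monomial_divides(lm, mono):
                factor_m = monomial_div(mono, lm)
                factor_c = coeff / lc
                for gm, gc in g.terms.items():
                    m = monomial_mul(gm, factor_m)
                    c = work.get(m, Fraction(0)) - gc * factor_c
                    if m == mono:
                        c += coeff  # the cancelled head itself
                    if c:
                        work[m] = c
                    else:
                        work.pop(m, None)
                break
        else:
            remainder[mono] = remainder.get(mono, Fraction(0)) + coeff
    return Polynomial(variables, remainder)


def s_polynomial(p: Polynomial, q: Polynomial, order: LexOrder) -> Polynomial:
    """S-polynomial: the lcm-scaled combination cancelling both heads."""
    if p.is_zero or q.is_zero:
        raise ValueError("S-polynomial of a zero polynomial")
    lmp, lmq = p.leading_monomial(order), q.leading_monomial(order)
    lcm = monomial_lcm(lmp, lmq)
    mp = Polynomial(p.variables, {monomial_div(lcm, lmp):
                                  Fraction(1) / p.leading_coefficient(order)})
    mq = Polynomial(q.variables, {monomial_div(lcm, lmq):
                                  Fraction(1) / q.leading_coefficient(order)})
    return mp * p - mq * q


def _interreduce(polys: list, order: LexOrder) -> list:
    """Reduce each element against the others; monic result, sorted."""
    polys = [g for g in polys if not g.is_zero]
    changed = True
    while changed:
        changed = False
        for i in range(len(polys)):
            rest = polys[:i] + polys[i + 1:]
            if not rest:
                continue
            r = poly_reduce(polys[i], rest, order)
            if r.terms != polys[i].terms:
                changed = True
                if r.is_zero:
                    polys.pop(i)
                else:
                    polys[i] = r
                break
    polys = [g.monic(order) for g in polys]
    polys.sort(key=lambda g: order.key(g.leading_monomial(order), g.variables))
    return polys


@dataclass
class GroebnerBasis:
    """Reduced, monic, inter-reduced lex basis.

    ``polynomials`` are sorted by ascending leading monomial, so the
    univariate element in the elimination (last-ranked) variable, when it
    exists, comes first.
    """

    polynomials: list
    order: LexOrder
    stats: dict = field(default_factory=dict)

    @property
    def variables(self):
        return self.polynomials[0].variables if self.polynomials else ()

    def reduce(self, p: Polynomial) -> Polynomial:
        return poly_reduce(p, self.polynomials, self.order)

    def contains(self, p: Polynomial) -> bool:
        """Ideal membership via reduction to zero."""
        return self.reduce(p).is_zero

    def univariate_element(self, var: str | None = None) -> Polynomial | None:
        """The basis element involving only ``var`` (default: last-ranked)."""
        var = var or self.order.elimination_variable
        for g in self.polynomials:
            used = g.used_variables()
            if used <= {var}:
                return g
        return None

    def is_zero_dimensional(self) -> bool:
        """Finitely many solutions iff every variable's pure power appears
        among the leading monomials."""
        heads = [g.leading_monomial(self.order) for g in self.polynomials]
        variables = self.variables
        for i, v in enumerate(variables):
            if not any(m[i] > 0 and all(e == 0 for j, e in enumerate(m) if j != i)
                       for m in heads):
                return False
        return True

    def to_sympy(self):
        return [g.to_sympy() for g in self.polynomials]


def buchberger(F: Sequence[Polynomial], order: LexOrder,
               max_pairs: int = 20000) -> GroebnerBasis:
    """Reduced Gröbner basis of ``<F>`` under ``order``.

    Pair selection follows the normal strategy (smallest lcm under the
    order first, ties broken by insertion index) so the run is
    deterministic.  Pairs with coprime leading monomials are skipped
    (Buchberger's first criterion).  ``max_pairs`` caps the number of
    S-pairs ever enqueued; lexicographic bases can blow up and a loud
    failure beats an endless one.
    """
    G = [f for f in F if not f.is_zero]
    if not G:
        raise ValueError("cannot take a Gröbner basis of the zero set")
    variables = G[0].variables
    for g in G:
        if g.variables != variables:
            raise ValueError("input polynomials over different variable tuples")
    G = [g.monic(order) for g in G]

    pairs = [(i, j) for i in range(len(G)) for j in range(i + 1, len(G))]
    enqueued = len(pairs)
    reductions = 0

    def pair_key(ij):
        i, j = ij
        lcm = monomial_lcm(G[i].leading_monomial(order),
                           G[j].leading_monomial(order))
        return (order.key(lcm, variables), i, j)

    while pairs:
        pairs.sort(key=pair_key)
        i, j = pairs.pop(0)
        lmi = G[i].leading_monomial(order)
        lmj = G[j].leading_monomial(order)
        if monomial_lcm(lmi, lmj) == monomial_mul(lmi, lmj):
            continue  # coprime heads: S-poly reduces to zero
        s = s_polynomial(G[i], G[j], order)
        r = poly_reduce(s, G, order)
        reductions += 1
        if not r.is_zero:
            G.append(r.monic(order))
            new = [(k, len(G) - 1) for k in range(len(G) - 1)]
            pairs.extend(new)
            enqueued += len(new)
            if enqueued > max_pairs:
                raise ResourceGuardError(
                    f"S-pair queue exceeded {max_pairs}; the lex basis for "
                    "this system is too large (try another variable order)")

    reduced = _interreduce(G, order)
    return GroebnerBasis(reduced, order,
                         stats={"pairs_enqueued": enqueued,
                                "reductions": reductions})


def _sympy_groebner(F: Sequence[Polynomial], order: LexOrder) -> GroebnerBasis:
    variables = F[0].variables
    syms = {v: sp.Symbol(v) for v in variables}
    gens = [syms[v] for v in order.ranking if v in variables]
    exprs = [f.to_sympy() for f in F]
    G = sp.groebner(exprs, *gens, order="lex")
    polys = [Polynomial.from_sympy(g, variables).monic(order) for g in G.exprs]
    polys.sort(key=lambda g: order.key(g.leading_monomial(order), g.variables))
    return GroebnerBasis(polys, order, stats={"backend": "sympy"})


def groebner_basis(F: Sequence[Polynomial], order: LexOrder,
                   backend: str = "internal",
                   max_pairs: int = 20000) -> GroebnerBasis:
    """Compute the reduced lex basis with the selected backend.

    ``backend`` is one of ``internal`` (own Buchberger), ``sympy`` (CAS
    routine) or ``both`` (compute both and assert they agree — used in the
    test suite, where the CAS acts as an independent oracle).
    """
    if backend == "internal":
        return buchberger(F, order, max_pairs=max_pairs)
    if backend == "sympy":
        return _sympy_groebner(F, order)
    if backend == "both":
        own = buchberger(F, order, max_pairs=max_pairs)
        ref = _sympy_groebner(F, order)
        if [g.terms for g in own.polynomials] != [g.terms for g in ref.polynomials]:
            raise GroebnerError("internal and sympy reduced bases disagree")
        return own
    raise ValueError(f"unknown backend {backend!r}")


@dataclass
class TriangularChain:
    """The elimination chain g1 (univariate), g2, ... of a lex basis.

    ``univariate`` lives in the elimination variable; ``stages`` lists, for
    each further variable in solving order, the basis elements that involve
    only already-solved variables plus that one.  A reduced basis may hold
    more than n polynomials; all are retained (extra elements act as
    consistency constraints during back-substitution).
    """

    univariate: Polynomial
    stages: list  # [(variable, [Polynomial, ...]), ...]
    order: LexOrder

    @property
    def solving_order(self):
        return [self.order.elimination_variable] + [v for v, _ in self.stages]

    def all_polynomials(self):
        out = [self.univariate]
        for _, gs in self.stages:
            out.extend(gs)
        return out


def extract_triangular(basis: GroebnerBasis) -> TriangularChain:
    """Organise a reduced lex basis into its triangular chain.

    Raises :class:`NotZeroDimensionalError` when the solution set is not
    finite and :class:`NoUnivariateError` when no element is univariate in
    the elimination variable (possible only in the non-zero-dimensional
    case, but kept as a distinct, catchable signal).
    """
    if not basis.is_zero_dimensional():
        raise NotZeroDimensionalError(
            "solution set is not finite; no triangular chain exists")
    g1 = basis.univariate_element()
    if g1 is None:
        raise NoUnivariateError(
            f"no basis element univariate in "
            f"{basis.order.elimination_variable!r}")
    solved = {basis.order.elimination_variable}
    remaining = [g for g in basis.polynomials if g is not g1]
    stages = []
    for var in reversed(basis.order.ranking[:-1]):
        if not any(var in g.used_variables() for g in basis.polynomials):
            continue
        group = [g for g in remaining
                 if g.used_variables() <= solved | {var}
                 and var in g.used_variables()]
        if not group:
            raise NoUnivariateError(
                f"triangular chain broken: no element introduces {var!r}")
        stages.append((var, group))
        solved.add(var)
        remaining = [g for g in remaining if g not in group]
    return TriangularChain(g1, stages, basis.order)


def univariate_in(F: Sequence[Polynomial], var: str,
                  backend: str = "internal",
                  max_pairs: int = 20000) -> Polynomial | None:
    """Univariate basis element in ``var``, recomputing with ``var`` last.

    Returns ``None`` (absence, not failure) when the ideal admits no
    univariate polynomial in ``var`` — i.e. when it is not
    zero-dimensional in the relevant direction.
    """
    variables = F[0].variables
    ranking = [v for v in variables if v != var] + [var]
    order = LexOrder(ranking)
    gb = groebner_basis(F, order, backend=backend, max_pairs=max_pairs)
    return gb.univariate_element(var)
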