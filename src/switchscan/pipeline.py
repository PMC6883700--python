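"""The end-to-end analysis: Gröbner basis -> triangular solve ->
admissibility -> Jacobian classification -> bistability verdict ->
per-output switchability.

Steady-state equation sets whose right-hand side factors as a state
variable times a residual polynomial (the ``Y * f3`` pattern of
substrate-annihilating networks) are split into branches: the ``Y = 0``
component and the cofactor component are analysed separately and the
verdict is taken per branch.  A branch with fewer than three admissible
states cannot carry bistability on its own; the verdict reported for the
system is that of the (unique) bistable branch, with the other branches'
states retained in the report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

from .groebner import (
    GroebnerBasis,
    LexOrder,
    NoUnivariateError,
    NotZeroDimensionalError,
    extract_triangular,
    groebner_basis,
)
from .models import PolynomialODESystem
from .polys import Polynomial
from .stability import (
    BistabilityVerdict,
    bistability_verdict,
    classify,
    jacobian,
)
from .steady_states import admissible_filter, back_substitute
from .switchability import (
    CubicCoefficients,
    NotCubic,
    SwitchabilityReport,
    decide_switchability,
    output_values_polynomial,
)


def monomial_variable_factors(p: Polynomial):
    """Split off the state variables dividing every term of ``p``.

    Returns (list of factored-out variable names with multiplicity 1 each,
    cofactor polynomial).  Only pure variable factors are extracted — the
    physically meaningful ``x * f(x)`` structure of a species that is
    absent-or-balanced — never a general polynomial factorisation.
    """
    if p.is_zero:
        return [], p
    factors = []
    terms = p.terms
    mins = [min(m[i] for m in terms) for i in range(len(p.variables))]
    cofactor_terms = {}
    for mono, coeff in terms.items():
        cofactor_terms[tuple(e - lo for e, lo in zip(mono, mins))] = coeff
    for v, lo in zip(p.variables, mins):
        factors.extend([v] * lo)
    return factors, Polynomial(p.variables, cofactor_terms)


def branch_equation_sets(system: PolynomialODESystem):
    """Enumerate the factor-component branches of the steady-state system.

    Each equation contributes its choices (each factored-out variable set
    to zero, or the cofactor vanishing); the branches are the Cartesian
    product.  Systems with no factorable equation yield the single branch
    ``main``.
    """
    variables = system.variables
    choice_lists = []
    for num in system.steady_state_equations():
        factors, cofactor = monomial_variable_factors(num)
        if factors and not cofactor.is_zero and cofactor.total_degree() > 0:
            choices = [(f"{v}=0", Polynomial.variable(variables, v))
                       for v in dict.fromkeys(factors)]
            choices.append(("", cofactor))
        elif factors:
            choices = [(f"{v}=0", Polynomial.variable(variables, v))
                       for v in dict.fromkeys(factors)]
        else:
            choices = [("", num)]
        choice_lists.append(choices)
    branches = []
    seen = set()
    for combo in itertools.product(*choice_lists):
        label = ",".join(sorted({tag for tag, _ in combo if tag})) or "main"
        eqs = tuple(p for _, p in combo)
        key = (label, tuple(frozenset(p.terms.items()) for p in eqs))
        if key in seen:
            continue
        seen.add(key)
        branches.append((label, list(eqs)))
    return branches


@dataclass
class BranchResult:
    label: str
    basis: GroebnerBasis | None
    records: list
    verdict: BistabilityVerdict | None
    error: str = ""


@dataclass
class AnalysisReport:
    """Everything the pipeline decided about one model."""

    model: str
    order: LexOrder
    branches: list
    verdict: BistabilityVerdict
    switchability: dict = field(default_factory=dict)
    bistable_branch: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def records(self):
        """Stability records of the verdict-carrying branch."""
        for br in self.branches:
            if br.label == self.bistable_branch:
                return br.records
        return [r for br in self.branches for r in br.records]

    @property
    def steady_states(self):
        return [r.state for r in self.records]

    def to_dict(self):
        d = {
            "model": self.model,
            "order": list(self.order.ranking),
            "verdict": self.verdict.to_dict(),
            "bistable_branch": self.bistable_branch,
            "branches": [],
            "switchability": {k: v.to_dict()
                              for k, v in self.switchability.items()},
            "metadata": dict(self.metadata),
        }
        for br in self.branches:
            entry = {"label": br.label, "error": br.error,
                     "states": [r.to_dict() for r in br.records]}
            if br.basis is not None:
                entry["basis"] = [
                    {"".join(f"{v}^{e}" for v, e in zip(g.variables, m) if e)
                     or "1": [c.numerator, c.denominator]
                     for m, c in g.terms.items()}
                    for g in br.basis.polynomials]
            if br.verdict is not None:
                entry["verdict"] = br.verdict.to_dict()
            d["branches"].append(entry)
        return d


def _solve_branch(label, equations, system, order, backend, max_pairs,
                  jac) -> BranchResult:
    eqs = [e for e in equations if not e.is_zero]
    if not eqs:
        return BranchResult(label, None, [], None,
                            error="degenerate branch: all equations vanish")
    try:
        gb = groebner_basis(eqs, order, backend=backend, max_pairs=max_pairs)
        if any(g.total_degree() == 0 for g in gb.polynomials):
            return BranchResult(label, gb, [], None,
                                error="inconsistent branch (basis = {1})")
        chain = extract_triangular(gb)
    except NotZeroDimensionalError as exc:
        return BranchResult(label, None, [], None, error=str(exc))
    except NoUnivariateError as exc:
        return BranchResult(label, None, [], None, error=str(exc))
    states = back_substitute(chain, branch=label)
    admissible = admissible_filter(states, system)
    records = [classify(s, jac) for s in admissible]
    records.sort(key=lambda r: r.state.value(order.elimination_variable))
    verdict = bistability_verdict(records)
    return BranchResult(label, gb, records, verdict)


def resolve_order(system: PolynomialODESystem, order=None,
                  univariate_var: str | None = None) -> LexOrder:
    """Lex ranking over the system variables, elimination variable last."""
    if isinstance(order, LexOrder):
        ranking = [v for v in order.ranking if v in system.variables]
    elif order:
        ranking = [v for v in order if v in system.variables]
        missing = [v for v in system.variables if v not in ranking]
        ranking = missing + ranking
    else:
        ranking = list(system.variables)
    if univariate_var is not None:
        ranking = [v for v in ranking if v != univariate_var] + [univariate_var]
    return LexOrder(ranking)


def analyze_system(system: PolynomialODESystem, outputs=None, order=None,
                   backend: str = "internal", max_pairs: int = 20000,
                   with_switchability: bool = True) -> AnalysisReport:
    """Run the full pipeline on a built system.

    ``order`` is the lex ranking (univariate element appears in its last
    variable); ``outputs`` defaults to every state variable.
    """
    lex = resolve_order(system, order)
    jac = jacobian(system)
    branches = [
        _solve_branch(label, eqs, system, lex, backend, max_pairs, jac)
        for label, eqs in branch_equation_sets(system)
    ]
    bistable = [br for br in branches if br.verdict and br.verdict.is_bistable]
    if len(bistable) == 1:
        verdict = bistable[0].verdict
        carrier = bistable[0]
    elif len(bistable) > 1:
        verdict = BistabilityVerdict(
            "inconclusive",
            sum(len(br.records) for br in bistable),
            detail="more than one factor branch is bistable")
        carrier = bistable[0]
    else:
        counts = sum(len(br.records) for br in branches)
        if any(br.verdict and br.verdict.status == "inconclusive"
               for br in branches):
            verdict = BistabilityVerdict("inconclusive", counts,
                                         detail="marginal eigenvalues")
        else:
            verdict = BistabilityVerdict(
                "not_bistable", counts,
                detail="no factor branch has the (S, U, S) triple")
        carrier = None

    report = AnalysisReport(
        model=system.name, order=lex, branches=branches, verdict=verdict,
        bistable_branch=carrier.label if carrier else "",
        metadata={"backend": backend},
    )
    if with_switchability:
        outputs = list(outputs) if outputs else list(system.variables)
        eqs = None
        if carrier is not None:
            for label, es in branch_equation_sets(system):
                if label == carrier.label:
                    eqs = es
                    break
        for out in outputs:
            report.switchability[out] = _switchability_for(
                out, eqs, carrier, verdict, lex, backend, max_pairs)
    return report


def _switchability_for(output, equations, carrier, verdict, lex, backend,
                       max_pairs) -> SwitchabilityReport:
    univariate = None
    if carrier is not None and equations is not None:
        try:
            sub_order = LexOrder(
                [v for v in lex.ranking if v != output] + [output])
            gb = groebner_basis(equations, sub_order, backend=backend,
                                max_pairs=max_pairs)
            univariate = gb.univariate_element(output)
        except Exception:
            univariate = None
    records = carrier.records if carrier else []
    rep = decide_switchability(output, univariate, records, verdict)
    if carrier is not None and verdict.is_bistable:
        try:
            rep.admissible_cubic = CubicCoefficients.from_polynomial(
                output_values_polynomial(records, output))
        except NotCubic:
            rep.admissible_cubic = None
    return rep
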