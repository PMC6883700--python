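"""Jacobian linearisation and the bistability verdict.

A steady state is stable when every eigenvalue of the Jacobian
J = d(f/d)/dx has negative real part, unstable when some real part is
positive.  Fixed-point bistability demands exactly three admissible
distinct steady states labelled (stable, unstable, stable); failing the
three-solution necessary condition already rules bistability out, and any
marginal eigenvalue (|Re| below threshold) leaves the verdict
inconclusive because linearisation is silent there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import PolynomialODESystem
from .polys import Polynomial
from .steady_states import SteadyState

MARGINAL_TOL = 1e-9


def jacobian(system: PolynomialODESystem) -> list:
    """Symbolic Jacobian of f_i/d_i as (numerator, denominator) pairs.

    Quotient rule: d(f/d)/dx = (f' d - f d') / d^2; only ever evaluated
    where d != 0 (admissibility has already excluded the poles).
    """
    rows = []
    for num, den in zip(system.rhs_numerators, system.rhs_denominators):
        row = []
        for v in system.variables:
            if den.total_degree() <= 0:
                c = den.terms.get((0,) * len(system.variables))
                row.append((num.diff(v) * (1 / c), Polynomial.constant(
                    system.variables, 1)))
            else:
                row.append((num.diff(v) * den - num * den.diff(v), den * den))
        rows.append(row)
    return rows


def evaluate_jacobian(jac, state: SteadyState) -> np.ndarray:
    point = state.as_floats()
    n = len(jac)
    J = np.empty((n, n))
    for i, row in enumerate(jac):
        for j, (num, den) in enumerate(row):
            p = {v: point.get(v, 0.0) for v in num.variables}
            J[i, j] = float(num.evaluate(p)) / float(den.evaluate(p))
    return J


@dataclass
class StabilityRecord:
    state: SteadyState
    eigenvalues: list
    label: str  # stable | unstable | marginal

    def to_dict(self):
        return {
            "values": {k: float(v) for k, v in self.state.values.items()},
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "label": self.label,
        }


def classify(state: SteadyState, jac, tol: float = MARGINAL_TOL
             ) -> StabilityRecord:
    """Label a steady state by the eigenvalues of the Jacobian there."""
    J = evaluate_jacobian(jac, state)
    eig = np.linalg.eigvals(J)
    re = eig.real
    if np.max(np.abs(re)) <= tol or abs(np.max(re)) <= tol:
        # the decisive eigenvalue sits on the imaginary axis: linearisation
        # is silent, refuse to guess
        label = "marginal"
    elif np.max(re) < -tol:
        label = "stable"
    else:
        label = "unstable"
    return StabilityRecord(state, [complex(z) for z in eig], label)


@dataclass
class BistabilityVerdict:
    status: str  # bistable | not_bistable | inconclusive
    admissible_count: int
    pattern: list = field(default_factory=list)
    detail: str = ""

    @property
    def is_bistable(self) -> bool:
        return self.status == "bistable"

    def to_dict(self):
        return {"status": self.status,
                "admissible_count": self.admissible_count,
                "pattern": list(self.pattern), "detail": self.detail}


def bistability_verdict(records: list) -> BistabilityVerdict:
    """Fixed-point bistability: exactly three admissible distinct states,
    two stable and one unstable.

    Fewer or more than three admissible states is `not_bistable` (the
    definition is strict; higher multistability is reported by count, not
    adjudicated).  A marginal label among three states is `inconclusive`.
    """
    n = len(records)
    labels = [r.label for r in records]
    if n != 3:
        return BistabilityVerdict(
            "not_bistable", n, labels,
            detail=f"{n} admissible steady state(s); three are required")
    if "marginal" in labels:
        return BistabilityVerdict(
            "inconclusive", n, labels,
            detail="an eigenvalue sits on the stability threshold")
    if labels.count("stable") == 2 and labels.count("unstable") == 1:
        return BistabilityVerdict("bistable", n, labels)
    return BistabilityVerdict(
        "not_bistable", n, labels,
        detail="three states but not the (stable, unstable, stable) pattern")
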