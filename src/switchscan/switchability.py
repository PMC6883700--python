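"""Output switchability: does a state variable differ between the two
stable steady states of a bistable system?

The decision rules are shortcuts read off the univariate basis polynomial
in the output variable; the ground truth is always the definition itself
(compare the output values at the two stable states), and the two must
agree.

For a cubic univariate  g1(x) = -x^3 + b x^2 - c x + d  the conditions

    b > 0,  c > 0,  d >= 0,   D = -27 d^2 + 18 b c d - 4 c^3 - 4 b^3 d
                                  + b^2 c^2 > 0

guarantee three distinct nonnegative roots (Descartes' rule of signs on
g1(-x) forbids negative roots; positive discriminant forces three distinct
real ones), hence a switchable output.  When the univariate polynomial
has repeated or too few roots, the output switches only if the repeated
value belongs to the unstable state; when no univariate polynomial exists
for the output, or its degree is not three, the comparison falls back to
the output values obtained from a different elimination order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .polys import Polynomial
from .steady_states import real_roots

DISTINCT_TOL = 1e-8


def discriminant(b, c, d) -> Fraction:
    """Discriminant of -x^3 + b x^2 - c x + d (equals that of the monic
    cubic with the same roots); positive iff three distinct real roots."""
    b, c, d = Fraction(b), Fraction(c), Fraction(d)
    return (-27 * d ** 2 + 18 * b * c * d - 4 * c ** 3
            - 4 * b ** 3 * d + b ** 2 * c ** 2)


class NotCubic(Exception):
    """Signal (not a failure): the univariate element is not degree 3."""


@dataclass
class CubicCoefficients:
    """Normalised cubic -x^3 + b x^2 - c x + d and its discriminant."""

    b: Fraction
    c: Fraction
    d: Fraction

    def __post_init__(self):
        self.b, self.c, self.d = (Fraction(self.b), Fraction(self.c),
                                  Fraction(self.d))

    @property
    def D(self) -> Fraction:
        return discriminant(self.b, self.c, self.d)

    def polynomial(self, var: str = "x") -> Polynomial:
        return Polynomial((var,), {(3,): Fraction(-1), (2,): self.b,
                                   (1,): -self.c, (0,): self.d})

    @classmethod
    def from_polynomial(cls, p: Polynomial) -> "CubicCoefficients":
        used = p.used_variables()
        if len(used) != 1:
            raise NotCubic("not univariate")
        coeffs = p.univariate_coefficients()
        if len(coeffs) != 4:
            raise NotCubic(f"degree {len(coeffs) - 1}, not 3")
        a = coeffs[0]
        scale = Fraction(-1) / a  # normalise leading coefficient to -1
        a3, a2, a1, a0 = [c * scale for c in coeffs]
        return cls(b=a2, c=-a1, d=a0)


def cubic_switch_test(p: Polynomial):
    """Apply the sign and discriminant conditions to a cubic univariate.

    Returns (CubicCoefficients, passed).  Non-cubic input raises
    :class:`NotCubic`, which routes the caller to the fallback comparison.
    """
    coeffs = CubicCoefficients.from_polynomial(p)
    passed = (coeffs.b > 0 and coeffs.c > 0 and coeffs.d >= 0
              and coeffs.D > 0)
    return coeffs, passed


def repeated_root_rule(root_values, stable_values, unstable_value,
                       tol: float = DISTINCT_TOL) -> bool:
    """Switchable only if the repetition involves the unstable state.

    ``root_values`` are the distinct values the output takes across the
    steady states (fewer than the number of states when repeated);
    switchability requires the two stable-state values to differ, i.e. the
    repeated value must be the unstable one's.
    """
    s1, s2 = stable_values
    stable_differ = abs(float(s1) - float(s2)) > tol * (1 + abs(float(s1)))
    return stable_differ


@dataclass
class SwitchabilityReport:
    output: str
    switchable: str  # yes | no | undefined
    rule_applied: str  # cubic-conditions | repeated-root |
    #                    fallback-comparison | not-bistable
    output_values_at_stable_states: tuple | None = None
    cubic: CubicCoefficients | None = None
    admissible_cubic: CubicCoefficients | None = None
    univariate_degree: int | None = None
    notes: str = ""

    def to_dict(self):
        d = {"output": self.output, "switchable": self.switchable,
             "rule_applied": self.rule_applied, "notes": self.notes}
        if self.output_values_at_stable_states is not None:
            d["output_values_at_stable_states"] = [
                float(v) for v in self.output_values_at_stable_states]
        if self.cubic is not None:
            d["cubic"] = {"b": float(self.cubic.b), "c": float(self.cubic.c),
                          "d": float(self.cubic.d), "D": float(self.cubic.D)}
        if self.admissible_cubic is not None:
            ac = self.admissible_cubic
            d["admissible_cubic"] = {"b": float(ac.b), "c": float(ac.c),
                                     "d": float(ac.d), "D": float(ac.D)}
        if self.univariate_degree is not None:
            d["univariate_degree"] = self.univariate_degree
        return d


def output_values_polynomial(records, output: str) -> Polynomial:
    """Monic polynomial (normalised to leading -1 for odd degree) whose
    roots are the output values at the admissible steady states.

    This is the univariate basis polynomial restricted to the admissible
    branch of the variety: when the elimination ideal is radical and every
    solution is admissible the two coincide, and when clearing rate-law
    denominators has inflated the univariate element with inadmissible
    roots this is the polynomial the steady states actually obey.
    """
    values = [r.state.values.get(output) for r in records]
    p = Polynomial.constant((output,), 1)
    xv = Polynomial.variable((output,), output)
    for v in values:
        v = v if isinstance(v, Fraction) else Fraction(float(v))
        p = p * (xv - Polynomial.constant((output,), v))
    if len(values) % 2 == 1:
        p = p * -1
    return p


def decide_switchability(output: str, univariate: Polynomial | None,
                         records, verdict,
                         tol: float = DISTINCT_TOL) -> SwitchabilityReport:
    """Route one output through the decision rules.

    (a) cubic univariate -> sign/discriminant conditions plus the check
        that the three roots are the three state values; (b) univariate
        with repeated/missing roots -> repeated-root rule; (c) univariate
        absent or of other degree -> direct comparison of the output values
        at the two stable states.  The direct comparison is also computed
        in every case as ground truth.
    """
    if verdict is None or not verdict.is_bistable:
        return SwitchabilityReport(
            output, "undefined", "not-bistable",
            notes="switchability is defined only for bistable systems")

    stable = [r for r in records if r.label == "stable"]
    unstable = [r for r in records if r.label == "unstable"]
    s_vals = tuple(r.state.values.get(output) for r in stable)
    u_val = unstable[0].state.values.get(output)
    definition_answer = abs(float(s_vals[0]) - float(s_vals[1])) > \
        tol * (1 + abs(float(s_vals[0])))

    if univariate is None:
        return SwitchabilityReport(
            output, "yes" if definition_answer else "no",
            "fallback-comparison", s_vals,
            notes="no univariate basis polynomial exists in this output; "
                  "values taken from another elimination order")

    degree = len(univariate.univariate_coefficients()) - 1
    roots = real_roots(univariate)
    n_states = len(records)
    distinct_roots = len(roots)
    repeated = (any(m > 1 for _, m in roots) or distinct_roots < n_states)

    if degree == 3 and not repeated:
        cubic, passed = cubic_switch_test(univariate)
        answer = passed and definition_answer
        return SwitchabilityReport(
            output, "yes" if answer else "no", "cubic-conditions",
            s_vals, cubic=cubic, univariate_degree=3)

    if repeated:
        answer = repeated_root_rule([r for r, _ in roots], s_vals, u_val, tol)
        cubic = None
        if degree == 3:
            cubic, _ = cubic_switch_test(univariate)
        return SwitchabilityReport(
            output, "yes" if answer else "no", "repeated-root", s_vals,
            cubic=cubic, univariate_degree=degree,
            notes="univariate roots repeat across the steady states")

    return SwitchabilityReport(
        output, "yes" if definition_answer else "no", "fallback-comparison",
        s_vals, univariate_degree=degree,
        notes=f"univariate element has degree {degree}; compared the "
              "output values at the stable states directly")
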