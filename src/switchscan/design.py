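"""Inverse design: from a target cubic to a realizing reaction network.

A switchable output obeys  dx/dt = -x^3 + b x^2 - c x + d  near steady
state, which reads as a generation/depletion imbalance

    g_generation = |b| x^2 + |d|        (autocatalytic + constant inflow)
    g_depletion  = x^3 + c x            (cooperative + first order)

A mass-action network realizing the cubic exactly: with a helper species
y (y = x^2 at steady state) the template

    S + Y -> 2X   (k1)      2X -> X + Y  (k2)
    X + Y -> Y+P  (k3)      X -> P       (k4)     [ + 0 -> X  (rate d) ]

with k1 = k2 = b, k3 = 1, k4 = c reduces, after substituting the y
balance, to exactly the target cubic in x.  The realization is not
unique; this template fixes the scaling so the cubic (not merely its root
set) is reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .models import Reaction, ReactionNetwork
from .polys import Polynomial
from .switchability import CubicCoefficients, cubic_switch_test


@dataclass
class RateDecomposition:
    generation: Polynomial  # |b| x^2 + |d|
    depletion: Polynomial   # x^3 + c x

    def imbalance(self) -> Polynomial:
        return self.generation - self.depletion


def decompose_rates(coeffs: CubicCoefficients,
                    var: str = "x") -> RateDecomposition:
    """Split the normalized cubic into generation and depletion rates."""
    v = (var,)
    x = Polynomial.variable(v, var)
    generation = x * x * abs(coeffs.b) + Polynomial.constant(v, abs(coeffs.d))
    depletion = x ** 3 + x * coeffs.c
    return RateDecomposition(generation, depletion)


class UnrealizableCubic(ValueError):
    pass


def realize_network(target: CubicCoefficients,
                    x: str = "x", helper: str = "y") -> ReactionNetwork:
    """Mass-action network whose reduced output dynamics is the target.

    Requires the target to pass the switchability conditions (three
    distinct nonnegative roots); a positive constant term d is realized as
    a zeroth-order inflow of the output species.
    """
    _, passed = cubic_switch_test(target.polynomial(x))
    if not passed:
        raise UnrealizableCubic(
            "target cubic fails the three-distinct-nonnegative-roots "
            f"conditions (b={target.b}, c={target.c}, d={target.d}, "
            f"D={target.D}); no bistable realization is attempted")
    b, c, d = target.b, target.c, target.d
    reactions = [
        Reaction({"S": 1, helper: 1}, {x: 2}, Fraction(b), "S+Y->2X"),
        Reaction({x: 2}, {x: 1, helper: 1}, Fraction(b), "2X->X+Y"),
        Reaction({x: 1, helper: 1}, {helper: 1, "P": 1}, Fraction(1),
                 "X+Y->Y+P"),
    ]
    if c > 0:
        reactions.append(Reaction({x: 1}, {"P": 1}, Fraction(c), "X->P"))
    if d > 0:
        reactions.append(Reaction({}, {x: 1}, Fraction(d), "0->X"))
    return ReactionNetwork(
        species=[x, helper, "S", "P"],
        reactions=reactions,
        boundary_species=["S", "P"],
        name=f"designed(b={b}, c={c}, d={d})",
    )
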