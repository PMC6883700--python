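"""Model definitions: the JSON dialect, loading, and the packaged systems.

A model JSON carries either a reaction list (mass-action kinetics) or
explicit right-hand-side expressions, plus exact parameters, conservation
constraints, an optional snap table for printed roundings, the preferred
lex ranking and the outputs of interest.  ``build_system`` turns a
definition (optionally with parameter overrides, e.g. along a bifurcation
scan) into an exact :class:`PolynomialODESystem`.

Seven classic bistable systems ship as fixtures: the minimal two-species
mass-action switch (``wilhelm``), the Edelstein network (``edelstein``),
two constructed networks with an unswitchable output (``example3``,
``example4``), and the AKT, MAPK (dual MEK phosphorylation) and RAS
signalling models (``akt``, ``mapk``, ``ras``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources

import sympy as sp

from .models import (
    ConservationConstraint,
    PolynomialODESystem,
    Reaction,
    ReactionNetwork,
    clear_denominators,
    eliminate_conserved,
    mass_action_odes,
    parse_rational_expression,
    rationalize,
)
from .polys import Polynomial

FIXTURE_NAMES = ("wilhelm", "edelstein", "example3", "example4",
                 "akt", "mapk", "ras")


@dataclass
class ModelDefinition:
    name: str
    variables: list
    parameters: dict = field(default_factory=dict)
    odes: dict | None = None            # var -> expression text
    reactions: list | None = None
    boundary: list = field(default_factory=list)
    constraints: list = field(default_factory=list)
    snap: dict = field(default_factory=dict)
    derived_parameters: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    order: list | None = None           # lex ranking, univariate var last
    scan: dict | None = None
    notes: str = ""

    @classmethod
    def from_dict(cls, data: dict) -> "ModelDefinition":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def resolved_parameters(self, overrides=None) -> dict:
        """Exact parameter map with snap and derived entries applied."""
        params = {}
        for k, v in self.parameters.items():
            params[k] = rationalize(v, snap=self.snap)
        if overrides:
            for k, v in overrides.items():
                if k not in params:
                    raise KeyError(f"unknown parameter {k!r}")
                params[k] = rationalize(v, snap=self.snap)
        if self.derived_parameters:
            syms = {k: sp.Rational(v.numerator, v.denominator)
                    for k, v in params.items()}
            for k, expr_text in self.derived_parameters.items():
                expr = parse_rational_expression(expr_text, snap=self.snap)
                value = sp.Rational(expr.subs(syms))
                params[k] = Fraction(int(value.p), int(value.q))
        return params


def load_model(path_or_dict) -> ModelDefinition:
    if isinstance(path_or_dict, dict):
        return ModelDefinition.from_dict(path_or_dict)
    with open(path_or_dict) as fh:
        return ModelDefinition.from_dict(json.load(fh))


def load_fixture(name: str) -> ModelDefinition:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{', '.join(FIXTURE_NAMES)}")
    text = (resources.files("switchscan") / "fixtures" / f"{name}.json"
            ).read_text()
    return ModelDefinition.from_dict(json.loads(text))


def _constraints(defn: ModelDefinition) -> list:
    out = []
    for c in defn.constraints:
        out.append(ConservationConstraint(
            coefficients={v: rationalize(x, snap=defn.snap)
                          for v, x in c["coeffs"].items()},
            total=rationalize(c["total"], snap=defn.snap),
            eliminate=c.get("eliminate")))
    return out


def build_system(defn: ModelDefinition, overrides=None) -> PolynomialODESystem:
    """Build the exact steady-state-ready system from a definition.

    Explicit ODE models are parsed with exact rational literals, the
    parameters substituted, denominators cleared, and each conservation
    constraint's designated variable eliminated.  Reaction models go
    through the mass-action assembler first.
    """
    params = defn.resolved_parameters(overrides)
    constraints = _constraints(defn)

    if defn.reactions is not None:
        network = ReactionNetwork(
            species=list(defn.variables) + list(defn.boundary),
            reactions=[Reaction(reactants=dict(r.get("reactants", {})),
                                products=dict(r.get("products", {})),
                                rate_constant=r["k"],
                                label=r.get("label", ""))
                       for r in defn.reactions],
            parameters=params,
            boundary_species=list(defn.boundary),
            name=defn.name)
        system = mass_action_odes(network)
    else:
        param_syms = {k: sp.Rational(v.numerator, v.denominator)
                      for k, v in params.items()}
        exprs = []
        for v in defn.variables:
            text = (defn.odes or {}).get(v, "0")
            expr = parse_rational_expression(text, snap=defn.snap)
            exprs.append(expr.subs(param_syms))
        system = clear_denominators(exprs, defn.variables, name=defn.name)

    system.parameters = params
    for constraint in constraints:
        victim = constraint.eliminate
        if victim is not None and victim in system.variables:
            system = eliminate_conserved(system, constraint, victim)
        else:
            system.constraints.append(constraint)
    return system
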