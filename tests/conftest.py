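import random
from fractions import Fraction

import pytest

from switchscan import (
    LexOrder,
    Polynomial,
    analyze_system,
    build_system,
    load_fixture,
)


@pytest.fixture(scope="session")
def rng():
    return random.Random(20240917)


def make_poly(variables, terms):
    """Shorthand: terms maps exponent tuples to coefficients."""
    return Polynomial(variables, {m: Fraction(c) for m, c in terms.items()})


def random_polynomial(rng, variables, max_degree=2, max_terms=4,
                      coeff_range=6):
    terms = {}
    for _ in range(rng.randint(1, max_terms)):
        mono = tuple(rng.randint(0, max_degree) for _ in variables)
        c = 0
        while c == 0:
            c = rng.randint(-coeff_range, coeff_range)
        terms[mono] = Fraction(c, rng.randint(1, 3))
    return Polynomial(variables, terms)


def random_system(rng, nvars=2, npolys=2, max_degree=2):
    variables = tuple("xyz"[:nvars])
    polys = []
    while len(polys) < npolys:
        p = random_polynomial(rng, variables, max_degree=max_degree)
        if not p.is_zero:
            polys.append(p)
    return variables, polys


@pytest.fixture(scope="session")
def wilhelm_report():
    defn = load_fixture("wilhelm")
    return analyze_system(build_system(defn), outputs=defn.outputs,
                          order=defn.order)


@pytest.fixture(scope="session")
def fixture_reports():
    """Analyses of every packaged model, computed once per session."""
    reports = {}
    for name in ("wilhelm", "edelstein", "example3", "example4",
                 "akt", "mapk", "ras"):
        defn = load_fixture(name)
        reports[name] = (defn, analyze_system(
            build_system(defn), outputs=defn.outputs, order=defn.order))
    return reports


@pytest.fixture
def wilhelm_equations():
    variables = ("x", "y")
    f1 = make_poly(variables, {(0, 1): 16, (2, 0): -1, (1, 1): -1,
                               (1, 0): Fraction(-3, 2)})
    f2 = make_poly(variables, {(2, 0): 1, (0, 1): -8})
    return variables, [f1, f2], LexOrder(("y", "x"))
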