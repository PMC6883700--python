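"""One-parameter scans and saddle-node bracketing.

Instead of numerical continuation, the exact pipeline is simply re-run on
a parameter grid (cheap at this problem scale) and the boundaries of the
bistable window — the limit points where two steady states coalesce — are
bracketed by bisection on the transition between one and three admissible
states.  When the univariate basis element is a cubic, the bisection can
equivalently track the sign change of its discriminant; both routes agree
to the requested resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .fixtures import ModelDefinition, build_system
from .pipeline import analyze_system
from .switchability import CubicCoefficients, NotCubic


@dataclass
class ScanPoint:
    value: Fraction
    admissible_count: int
    status: str
    outputs: dict = field(default_factory=dict)
    discriminant: float | None = None


@dataclass
class ScanResult:
    parameter: str
    grid: list
    boundaries: list = field(default_factory=list)  # (midpoint, halfwidth)
    resolution: float = 0.0

    def counts(self):
        return [p.admissible_count for p in self.grid]

    def to_dict(self):
        return {
            "parameter": self.parameter,
            "resolution": self.resolution,
            "grid": [{"value": float(p.value),
                      "admissible_count": p.admissible_count,
                      "status": p.status,
                      "outputs": {k: [float(x) for x in v]
                                  for k, v in p.outputs.items()},
                      "discriminant": p.discriminant}
                     for p in self.grid],
            "boundaries": [[float(m), float(w)] for m, w in self.boundaries],
        }


def _point(defn: ModelDefinition, parameter: str, value: Fraction,
           backend: str) -> ScanPoint:
    system = build_system(defn, overrides={parameter: value})
    report = analyze_system(system, order=defn.order, backend=backend,
                            with_switchability=False)
    outputs = {}
    for v in system.variables:
        outputs[v] = sorted(r.state.value(v) for r in report.records)
    disc = None
    for br in report.branches:
        if br.basis is None:
            continue
        uni = br.basis.univariate_element()
        if uni is None:
            continue
        try:
            disc = float(CubicCoefficients.from_polynomial(uni).D)
        except NotCubic:
            pass
        if br.label == report.bistable_branch or br.label == "main":
            break
    return ScanPoint(value, len(report.records), report.verdict.status,
                     outputs, disc)


def scan(defn: ModelDefinition, parameter: str | None = None,
         lo=None, hi=None, npoints: int | None = None,
         backend: str = "internal") -> ScanResult:
    """Admissible-state count and verdict along a parameter grid."""
    spec = defn.scan or {}
    parameter = parameter or spec.get("parameter")
    if parameter is None:
        raise ValueError("no scan parameter given or declared by the model")
    if parameter not in defn.parameters:
        raise ValueError(f"parameter {parameter!r} not in the model")
    lo = Fraction(lo if lo is not None else Fraction(str(spec.get("lo"))))
    hi = Fraction(hi if hi is not None else Fraction(str(spec.get("hi"))))
    npoints = npoints or int(spec.get("points", 21))
    if not lo < hi:
        raise ValueError("need lo < hi")
    step = (hi - lo) / (npoints - 1)
    grid = [_point(defn, parameter, lo + i * step, backend)
            for i in range(npoints)]
    return ScanResult(parameter, grid)


def bracket_boundaries(defn: ModelDefinition, result: ScanResult,
                       resolution: float = 1e-3,
                       backend: str = "internal",
                       use_discriminant: bool | None = None) -> ScanResult:
    """Bisect every count transition of a scan down to ``resolution``.

    With a cubic univariate element the discriminant's sign change marks
    the limit point and is used as the bisection predicate; otherwise the
    admissible-count change itself is.  Boundaries are reported as
    (interval midpoint, halfwidth).
    """
    grid = result.grid
    boundaries = []
    for a, b in zip(grid, grid[1:]):
        if a.admissible_count == b.admissible_count:
            continue
        lo, hi = a.value, b.value
        if use_discriminant is None:
            by_disc = (a.discriminant is not None
                       and b.discriminant is not None
                       and (a.discriminant > 0) != (b.discriminant > 0))
        else:
            by_disc = use_discriminant

        def pred(point: ScanPoint):
            if by_disc:
                return (point.discriminant or 0.0) > 0
            return point.admissible_count == a.admissible_count

        ref = pred(a)
        while float(hi - lo) > resolution:
            mid = (lo + hi) / 2
            p = _point(defn, result.parameter, mid, backend)
            if pred(p) == ref:
                lo = mid
            else:
                hi = mid
        boundaries.append(((lo + hi) / 2, (hi - lo) / 2))
    result.boundaries = boundaries
    result.resolution = resolution
    return result
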