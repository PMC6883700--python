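"""Numerical trajectories and the one-dimensional output dynamics.

A fixed-step classical Runge-Kutta integrator is all these small smooth
systems need; trajectories are tagged with the admissible steady state
they converge to (if any).  For a bistable system with a switchable
output the cubic univariate basis element defines a one-dimensional
surrogate  dx/dt = -x^3 + b x^2 - c x + d  whose fixed points are the
output's steady-state values and whose trajectories reach the same stable
value as the full system started in the same basin — transients differ,
attractors agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .models import PolynomialODESystem
from .polys import Polynomial
from .switchability import CubicCoefficients

CONVERGENCE_TOL = 1e-8


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray          # shape (nt, nvars)
    variables: tuple
    converged_to: dict | None   # nearest admissible steady state, if any
    truncated: bool = False     # a rate-law denominator vanished en route

    @property
    def terminal_state(self) -> dict:
        return dict(zip(self.variables, self.states[-1]))

    def component(self, var: str) -> np.ndarray:
        return self.states[:, self.variables.index(var)]


def _rhs_callable(system: PolynomialODESystem):
    import sympy as sp

    syms = sp.symbols(system.variables)
    fn = [sp.lambdify(syms, num.to_sympy(), "math")
          for num in system.rhs_numerators]
    fd = [sp.lambdify(syms, den.to_sympy(), "math")
          for den in system.rhs_denominators]

    def f(state):
        args = tuple(state)
        out = np.empty(len(fn))
        for i, (n, d) in enumerate(zip(fn, fd)):
            dv = d(*args)
            if abs(dv) < 1e-12:
                raise ZeroDivisionError
            out[i] = n(*args) / dv
        return out

    return f


def integrate(system: PolynomialODESystem, x0, t_end: float = 100.0,
              step: float = 1e-3, steady_states=None,
              record_every: int = 10) -> Trajectory:
    """Classical fourth-order Runge-Kutta with a fixed step.

    ``steady_states`` (list of value maps) enables convergence tagging:
    the trajectory is marked converged only when the rhs norm at the
    terminal point is below tolerance and a steady state lies nearby.
    """
    variables = system.variables
    if isinstance(x0, dict):
        x = np.array([float(x0[v]) for v in variables])
    else:
        x = np.asarray(x0, dtype=float)
    if np.any(x < 0):
        raise ValueError("initial condition must be componentwise nonnegative")
    f = _rhs_callable(system)
    n_steps = int(round(t_end / step))
    times = [0.0]
    states = [x.copy()]
    truncated = False
    for i in range(n_steps):
        try:
            k1 = f(x)
            k2 = f(x + 0.5 * step * k1)
            k3 = f(x + 0.5 * step * k2)
            k4 = f(x + step * k3)
        except ZeroDivisionError:
            truncated = True
            break
        x = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if (i + 1) % record_every == 0 or i == n_steps - 1:
            times.append((i + 1) * step)
            states.append(x.copy())
    converged = None
    if not truncated:
        try:
            rate = np.linalg.norm(f(x))
        except ZeroDivisionError:
            rate = np.inf
        if rate < CONVERGENCE_TOL * max(1.0, float(np.max(np.abs(x)))):
            if steady_states:
                best, dist = None, np.inf
                for ss in steady_states:
                    ref = np.array([float(ss[v]) for v in variables])
                    d = float(np.max(np.abs(ref - x)))
                    if d < dist:
                        best, dist = ss, d
                if best is not None and dist < 1e-4 * (1 + np.max(np.abs(x))):
                    converged = dict(best)
            else:
                converged = dict(zip(variables, x))
    return Trajectory(np.array(times), np.array(states), variables,
                      converged, truncated)


def univariate_system(coeffs: CubicCoefficients,
                      var: str = "x") -> PolynomialODESystem:
    """The 1-D surrogate dx/dt = -x^3 + b x^2 - c x + d.

    Its fixed points are the cubic's roots; with three distinct roots the
    outer two are stable (negative slope) and the middle one unstable.
    """
    p = coeffs.polynomial(var)
    return PolynomialODESystem(
        variables=(var,),
        rhs_numerators=[p],
        rhs_denominators=[Polynomial.constant((var,), 1)],
        name=f"univariate[{var}]")


def same_attractor_check(system: PolynomialODESystem,
                         one_d: PolynomialODESystem,
                         x0: dict, output: str,
                         t_end: float = 100.0, step: float = 1e-3,
                         tol: float = 1e-4) -> bool:
    """Do the full system and its 1-D output surrogate reach the same
    stable output value from the same initial output level?"""
    full = integrate(system, x0, t_end=t_end, step=step)
    v0 = float(x0[output]) if isinstance(x0, dict) else float(x0)
    oned_var = one_d.variables[0]
    small = integrate(one_d, {oned_var: v0}, t_end=t_end, step=step)
    a = full.terminal_state[output]
    b = small.terminal_state[oned_var]
    return abs(a - b) <= tol * (1.0 + abs(a))
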