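# Methods

## Model normalisation

Models enter either as mass-action reaction lists or as explicit
right-hand sides over the grammar `+ − * / ^` with decimal or fraction
literals. Every coefficient is converted to an exact rational before any
algebra: reduced lexicographic Gröbner bases are unique only over an
exact field, and the integer-coefficient bases of the packaged systems
(e.g. `x³ − 8x² + 12x`) are reproducible coefficient-for-coefficient only
in rational arithmetic. Decimal-to-rational conversion is literal
(`1.5 → 3/2`); where a model's printed constants are themselves roundings
of exact values, the model declares an explicit **snap table**
(`0.166 → 1/6`, `1.667 → 5/3` in the inflow network) that is applied at
the literal level. Snap tables are versioned data in the fixture file,
never a heuristic.

Rational rate laws (Michaelis–Menten terms in the AKT, MEK and RAS
models) are normalised by `sympy`'s rational-function canonicalisation
into numerator/denominator polynomial pairs `f_i/d_i` with no common
factor; steady-state analysis uses `f_i = 0` with `d_i ≠ 0` enforced
later. Linear conservation laws (`x₂ + x₃ = c`, `x + y + z = 1`, the two
RAS totals) eliminate a designated victim variable by exact substitution;
the linear expression is retained so the eliminated species can be
restored and required nonnegative when states are filtered. In the RAS
fixture the constraint coefficients α/β = 0.05 are written out from the
declared totals α = 10, β = 200.

## Gröbner engine

The Buchberger completion is implemented here over `Fraction`
coefficients: multivariate division with deterministic head selection,
S-polynomials, the normal (smallest-lcm) pair strategy with index
tie-break, the coprime-leading-term criterion, inter-reduction and monic
normalisation. The reduced basis is unique for a fixed lex ranking, so
runs are bit-reproducible; a configurable S-pair cap (default 20 000)
fails loudly on lex blow-up rather than hanging. The convention
throughout: "univariate in v" means v is ranked **last**; the packaged
models each declare their ranking. `sympy.groebner` is wired in as an
alternative backend, and `backend="both"` computes both and asserts
term-by-term equality — the test suite uses this as an independent CAS
oracle on every fixture and on random systems, while the CLI and the
acceptance script run the internal engine.

Printed bases in the sources are compared up to a nonzero scalar (our
bases are monic; published ones often are not).

## Solving and filtering

The triangular chain is read off the reduced basis (univariate element
first, then elements grouped by the variable they introduce; extra
elements are kept as consistency constraints). Univariate real roots are
isolated exactly — square-free decomposition with Sturm-style counting as
provided by `sympy`'s certified `real_roots` — with rational roots kept
exact and irrational ones refined to double precision. Back-substitution
extends each root branch-by-branch; when several chain elements constrain
the same new variable their root sets are intersected, an element that
degenerates to zero under the partial assignment contributes no
constraint, and every completed assignment must null every chain element.

Admissibility then applies the biology: components real
(|Im| < 1e−9·(1+|Re|)) and ≥ −1e−9, pairwise ∞-norm distinct at relative
1e−8, every rate-law denominator nonzero, and eliminated conserved
species nonnegative. These tolerances are not from any source; they are
safe because the chain is exact and roots are accurate to machine
precision. The denominator and conserved-moiety checks do real work: in
the MEK cycle the univariate element is a quartic whose fourth real root
carries z = 1 − x − y < 0, and in the RAS model clearing the
Michaelis–Menten denominators inflates the univariate element to degree
eight, five of whose roots have negative components — all are filtered,
leaving the physical triple.

## Stability and the bistability verdict

Jacobians of `f_i/d_i` are formed symbolically by the quotient rule on
the exact polynomials and evaluated numerically; eigenvalues come from
`numpy`. A state is stable when every real part is below −1e−9, unstable
when some real part exceeds +1e−9; any eigenvalue inside that band makes
the state *marginal* and the verdict *inconclusive* — linearisation is
silent there and the package does not guess. Fixed-point bistability
demands exactly three admissible distinct states labelled
(stable, unstable, stable); fewer states fail the necessary condition,
and more than three are reported by count but not adjudicated.

### Factor branches

A right-hand side of the form `Y·f₃` (a species that is either absent or
balanced) makes the steady-state variety a union of components. The
pipeline splits equations only at such **pure variable factors** — never
at a general polynomial factorisation, which would scatter legitimate
root triples across branches — and analyses each branch separately:
Gröbner basis, solve, filter, classify against the *original* system's
Jacobian. The verdict is taken per branch: a branch with a single
admissible state cannot carry bistability, and the system verdict is that
of the unique bistable branch, with other branches' states retained in
the report. In the inflow network the `Y = 0` branch holds one positive
state (Z ≈ 6.559) and the cofactor branch the bistable triple.

## Switchability

The defining test — do the two stable states differ in the output? — is
always computed. The rules are shortcuts that must agree with it (a test
asserts this on every fixture):

1. **Cubic conditions.** If the univariate basis polynomial in the output
   is a cubic with three distinct roots, normalise to leading −1 and
   require b > 0, c > 0, d ≥ 0 and D > 0. Descartes' rule on `g₁(−x)`
   forbids negative roots; D > 0 forces three distinct real ones. The
   boundary d = 0 (a root exactly at 0) is accepted.
2. **Repeated-root rule.** If the univariate polynomial has repeated
   roots, or fewer roots than the system has states, the output switches
   only if the repetition involves the unstable state.
3. **Fallback comparison.** If the univariate polynomial is absent (the
   ideal is not zero-dimensional in that direction) or has degree ≠ 3
   with all roots distinct, compare the output values at the two stable
   states directly. The MEK cycle (quartic) and RAS (octic) take this
   route.

Switchability is *undefined* for systems that are not (or only
marginally) bistable.

For reporting, the pipeline also forms the **admissible output
polynomial**: the monic polynomial (normalised to leading −1 for odd
degree) whose roots are the output values at the admissible states. When
every solution of the elimination ideal is admissible it coincides with
the univariate basis element; when denominator-clearing has inflated the
variety it is the polynomial the physical states actually obey — for the
RAS model this is the cubic with quadratic coefficient 0.91217 whose
coefficients summarise the switch.

## Parameter scans

Saddle-node (limit-point) boundaries of the bistable window are found by
re-running the exact pipeline on a parameter grid and bisecting each
admissible-count transition to a requested resolution (default 1e−3),
reported as interval midpoint ± halfwidth. When the univariate element is
a cubic at both bracket ends, the sign change of its discriminant is used
as the bisection predicate; otherwise the count change itself. The two
predicates agree to the resolution (tested on a shifted cubic normal form
with closed-form limit points ±2/(3√3)). Grid-then-bisection replaces
pseudo-arclength continuation deliberately: per-point analysis is cheap
at this scale, exact, and free of continuation machinery; Hopf
bifurcations and limit cycles are out of scope.

## Dynamics

Trajectories use a fixed-step classical Runge–Kutta scheme (default step
1e−3 time units, horizon 100), with rate-law denominators guarded along
the path and convergence tagged only when the rhs norm falls below 1e−8.
For a switchable output the cubic defines the one-dimensional surrogate
`dx/dt = g₁(x)` whose fixed points are the output's steady-state values —
outer roots stable, middle root unstable. Surrogate and full system agree
on the attractor reached from a shared starting output value; tests
sample basins away from the separatrix (within 1e−3 of it no claim is
made) and check the full system against an adaptive `scipy` integrator.

## Inverse design

A passing cubic splits into generation `|b|x² + |d|` and depletion
`x³ + cx`. The synthesis template (autocatalytic pair S+Y→2X, 2X→X+Y with
k₁ = k₂ = b, the cubic-generating sink X+Y→Y+P with k₃ = 1, first-order
decay X→P with k₄ = c, and for d > 0 a zeroth-order inflow of rate d)
reduces, after substituting the helper's balance y = x², to exactly the
target cubic — the scaling freedom is resolved so the cubic itself, not
merely its root set, is reproduced; both choices are mathematically valid
realisations and the constants are overridable. Realised networks
round-trip: their univariate lex basis equals the target cubic exactly
(rational arithmetic), and the full pipeline verdicts them bistable and
switchable in the output.

## Known limitations

- Lexicographic bases can blow up beyond a handful of variables; the
  S-pair guard fails loudly and suggests reordering. Larger networks
  should be reduced (lumping, conservation elimination) first.
- Marginal (non-hyperbolic) states are never classified; parameter values
  sitting exactly on a fold return *inconclusive*.
- The repeated-root and fallback rules compare values at the resolution
  of the root refinement (1e−8 relative); outputs that differ more finely
  than that are reported as non-switchable.
- Only fixed-point bistability is treated: no limit cycles, Hopf
  bifurcations, stochastic switching, or basins beyond sampled
  trajectories.
- SBML import and rate-law libraries beyond explicit rational expressions
  are out of scope; models are written in the JSON dialect described in
  the README.
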