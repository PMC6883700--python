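# switchscan

Detection of bistability and output switchability in polynomial ODE models
of biochemical reaction networks, using exact lexicographic Gröbner bases.

## The problem

Cellular signalling pathways contain bistable switches: systems whose state
can rest in either of two stable steady states separated by an unstable
saddle. For a mass-action (or rational rate-law) model

```
dx/dt = f(x),      f polynomial (or f_i/d_i rational), x ≥ 0,
```

the steady states are the nonnegative real solutions of the polynomial
system `f(x) = 0`. A system is **fixed-point bistable** when it has exactly
three nonnegative distinct real steady states — two stable, one unstable —
as certified by the eigenvalues of the Jacobian `J = ∂f/∂xᵀ` at each state.

Bistability of the *state* does not make every *variable* a switch. An
output `xᵢ` is **switchable** only if its value differs at the two stable
steady states. `switchscan` decides both properties at once by computing
the reduced Gröbner basis of `⟨f₁,…,fₙ⟩` under a lexicographic order: the
basis is triangular, its univariate element `g₁` in the last-ranked
variable is solved by exact real-root isolation, the roots are extended
through the chain by back-substitution, and admissible states (real,
nonnegative, distinct, rate-law denominators nonzero, conserved moieties
nonnegative) are classified by `J`'s eigenvalues.

For the output itself, when the univariate basis polynomial is the cubic

```
g₁(x) = −x³ + b x² − c x + d,
```

the conditions `b > 0`, `c > 0`, `d ≥ 0` and positive discriminant

```
D = −27d² + 18bcd − 4c³ − 4b³d + b²c² > 0
```

guarantee three distinct nonnegative roots and hence a switchable output;
`|b|x² + |d|` is the generation rate and `x³ + cx` the depletion rate, a
reading that also drives the inverse problem (synthesising a mass-action
network that realises a target cubic). When the univariate polynomial has
repeated or missing roots the output switches only if the repetition
involves the unstable state, and when no cubic is available the defining
comparison — output values at the two stable states — decides.

All algebra runs over exact rationals (`fractions.Fraction`); the
Buchberger completion, multivariate division and triangular extraction are
implemented in this package, with `sympy.groebner` available as an
independent cross-check backend.

## Worked example

The packaged model `example3` is a two-variable reduced network whose
output `Y` is produced by two reactions drawing on a conserved pool, so
`Y` cannot switch even though the system is bistable:

```python
from switchscan import load_fixture, build_system, analyze_system

defn = load_fixture("example3")
report = analyze_system(build_system(defn), outputs=defn.outputs,
                        order=defn.order)
```

The reduced lex basis (monic) is triangular with univariate element in
`Y`:

```
Y^2 - 19*Y + 90
Z*Y - 9*Z - 2*Y + 18
Z^2 - 4*Z + Y - 6
```

Solving the chain and classifying by Jacobian eigenvalues:

```
{'Y': 9.0,  'Z': 1.0} stable    eigenvalues [-1.0, -2.0]
{'Y': 9.0,  'Z': 3.0} stable    eigenvalues [-1.0, -2.0]
{'Y': 10.0, 'Z': 2.0} unstable  eigenvalues [ 1.0, -1.0]
```

Three admissible states in the stable/unstable/stable pattern: the system
is bistable. The univariate polynomial in `Y` has only two roots {9, 10},
one fewer than the number of states, so a root repeats across states; the
repeated value 9 sits at **both stable** states, hence:

```
Y: no  (repeated-root rule; stable-state values 9 and 9)
Z: yes (cubic conditions;   stable-state values 1 and 3)
```

`Y` is a bistable system's unswitchable output — it returns to 9 whichever
attractor the state chooses — while `Z` switches between 1 and 3.

Seven models ship as fixtures: `wilhelm` (minimal two-species mass-action
switch), `edelstein`, `example3`, `example4` (inflow network whose
`Y`-balance factors as `Y·f₃`, analysed per branch), and the `akt`,
`mapk` (dual MEK phosphorylation) and `ras` signalling models. The same
machinery runs from the shell:

```
switchscan fixtures run example3
switchscan analyze mymodel.json --output Y
switchscan scan src/switchscan/fixtures/akt.json --param lam
switchscan design --b 8 --c 12 --d 0
```

`scan` re-runs the exact pipeline on a parameter grid and brackets the
saddle-node boundaries of the bistable window by bisection (for the AKT
model, the insulin window `λ ∈ [0.38, 0.65]`); `design` synthesises a
four-reaction network realising a target cubic exactly.

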