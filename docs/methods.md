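# Methods

## The model representation

A model is a directed acyclic dataflow graph. Term nodes carry a name and
a real value; expression nodes carry one operator and an ordered list of
input pins; assigner nodes bind the expression arriving on their single
pin as the right-hand side of one term's ODE. Links run from an output
pin to an input pin; output pins may fan out, input pins hold at most one
link. Cycles are rejected when a link is created, not at validation time:
dynamic feedback in an ODE system lives in the equations' references to
state-variable *values*, whereas a link cycle in the dataflow graph could
never be evaluated. A term is classified as a state variable exactly when
an assigner targets it, in which case its value is the initial condition;
all other terms are constants fixed for the whole run. One assigner per
variable is enforced at construction time, since two right-hand sides for
one ODE would be meaningless.

Orphan terms (connected to nothing, assigned nothing) are legal and
surface as validation *warnings*, not errors — a modeller may park
quantities on the canvas while thinking. Validation errors, which all
block simulation, are: unconnected expression pins (one finding per
pin), assigners with empty inputs, zero state variables, extension
operators with no loaded function, and non-finite term values.

## Expression semantics

An n-ary arithmetic node folds left-to-right in pin order:
`((p0 op p1) op p2) …`, so a subtract node over pins (a, b, c) means
`a - b - c` and a divide node means `a / b / c`. A single operator per
node with a deterministic, order-sensitive rule keeps a node's meaning
readable off the diagram.

Rendering joins operands with single-spaced operators (`a * b`) so
rendered equations are stable, diffable text. Parentheses are
precedence-driven and minimal in the following exact sense: a child is
parenthesized when its operator binds less tightly than its parent's,
*or equally tightly in a non-first position*. The second clause makes
rendering exactly invertible — parsing the text with ordinary
left-associative precedence rules recovers the very tree that was
rendered (up to re-folding of same-operator left chains, which is an
identity on both value and rendering). Dropping it would conflate, e.g.,
`a - (b + c)` with `(a - b) + c`. The renderer has a code mode used by
code generation: extension calls are always emitted in function-call
notation there, because display formats like `$1 ^ $2` need not be valid
host-language syntax.

Because the operator vocabulary is exactly `+ - * /`, there is no unary
minus. A right-hand side consisting of a single negative term is built
with the subtraction fold `x - x - x`, which equals `-x` exactly in IEEE
arithmetic (`x - x` is exactly zero, `0 - x` exactly `-x`). The bundled
classic SIR model uses this idiom for `dS/dt`.

Division by zero is detected explicitly during evaluation and reported
with the rendered text of the offending subexpression, so a failing
simulation names the term that failed rather than a solver internal.

## Numerical integration

`simulate` compiles the assigners' expression trees into a derivative
function and hands it to `scipy.integrate.solve_ivp`. The default method
is the adaptive explicit Runge–Kutta 5(4) pair with relative tolerance
1e-6 and absolute tolerance 1e-9; both tolerances and the method
(`LSODA`, `Radau`, … for stiff systems) are per-model configuration. The
user's time step defines only the *reporting grid*; the solver steps
adaptively underneath and the solution is interpolated onto the grid, so
halving the step refines reporting without changing integration
accuracy.

The grid is built by count, `n = floor((end - start)/Δt)` with a 1e-9
relative guard, as `start + k·Δt` — never by repeated accumulation — so
floating-point drift cannot change the number of points; the final point
is snapped to `end` when it lands there within `Δt·1e-9`. A degenerate
interval (`end == start`) yields the single-row result equal to the
initial conditions. The first reported row is set to the initial values
exactly.

## Code generation and the equivalence contract

The exported script is produced by substituting the model into a Jinja
template shipped with the package (`templates/simulation.py.jinja`);
users may supply an alternative template with the same placeholder
vocabulary (`populations`, `constants`, `odes`, `extension_sources`,
`sim`, `csv_path`), and a template missing a placeholder is rejected
with the placeholder's name. The generated script depends only on
numpy, scipy and matplotlib; it defines any extension functions (whole
plugin files are embedded verbatim, so decorated functions can still
call file-local helpers, with a no-op `@node` shim defined above them),
a `system(t, y, *constants)` derivative function that unpacks state
names and then constant names, the same grid construction as the
in-process path, the same solver call, and the same CSV formatting
(shortest round-trip `repr`).

Because both paths evaluate the same operation sequence on the same
floats — the in-process evaluator folds children in exactly the order
the rendered code parses to — the two trajectories are not merely close
but bit-identical; the contract is stated and tested as agreement within
1e-12 relative. Exported variable names pass through an identifier
sanitizer (non-identifier characters to underscores, leading-digit
prefix, numeric suffix on collision) that also avoids the script's own
names; a state variable literally named `y` is exported as `y_2` in the
script while keeping its display name everywhere else.

## Plugin nodes

An extension file is executed in a dedicated namespace providing the
`@node` decorator and `math`. Each decorated function becomes a node
kind; its positional-parameter count fixes the node's input-pin arity
(zero-parameter functions are rejected), and an optional
`format="$1 ^ $2"` string controls display rendering (placeholders may
repeat; out-of-range placeholders are a load error). Loading is always
explicit — a CLI flag or a model's recorded extension references, which
are stored relative to the model file so shared models travel with
their plugins. Name collisions across loaded files are errors.

## The bundled models and their parameters

No external datasets are involved; the four builders are the package's
study corpus. Their default parameters are constants of this package,
chosen once for the canonical qualitative behaviour of each system:

* **Classic SIR** (`b_d = 0.002`, `g = 0.1`, 999/1/0): basic
  reproduction number ≈ 20, a full epidemic sweep; `S + I + R` is
  conserved identically, which the tests check to 1e-8 relative
  (observed drift is at rounding level, ~1e-13 absolute on a
  population of 1000).
* **Extended SIR** (birth `b = 10`, death `n = 0.1`, direct and
  environmental transmission `b_d = 0.01`, `b_e = 0.005`, recovery
  `g = 0.2`, shedding `p = 1`, pathogen decay `c = 1`): endemic with a
  damped oscillatory approach to equilibrium. Summing the host
  equations gives `d(S+I+R)/dt = b - n(S+I+R)`, so the host total
  relaxes to `b/n` on the time scale `1/n`; tests integrate to
  `t = 15/n` and check the total to 0.5% under randomized positive
  parameter draws.
* **Immune regulation** (five variables N, M_reg, CH, AC, TD): the
  anti-inflammatory factor `(1 + α·AC)` *divides* the neutrophil source
  and the pro-inflammatory cytokine production. The printed form of this
  factor is typographically ambiguous between multiplication and
  division; division is the reading under which a stronger
  anti-inflammatory response suppresses inflammation, which is the
  stated role of AC, so the package implements inhibition-by-division —
  isolated in this one builder. The factor is built with the
  `inhibition(a, x) = 1 + a*x` plugin node shipped in the package data,
  so this model also exercises the extension path end to end. The
  symbols C and CH both denote the pro-inflammatory cytokine. Note the
  interior equilibrium has `TD* = β_N·m_Mreg/(k·γ)`; the defaults
  (γ = 0.5, k = 1.0, others 0.05–0.5) put the damage plateau below 1% of
  its peak — a resolved inflammation. Neutrophil dynamics keep both
  `-β_N·N` and `-m_N·N` as separate loss terms, as distinct activity and
  death processes.
* **Predator–prey** (Lotka–Volterra, α = 1.1, β = 0.4, δ = 0.1,
  γ = 0.4): the first integral `δx - γ·ln x + βy - α·ln y` is checked
  constant to 1e-3 relative at default tolerances, and the fixed point
  `(γ/δ, α/β)` stays put.

## Problem sizes and tolerances used in the checks

The acceptance checks simulate the bundled models over their default
horizons (a few hundred reporting points each), use 10 randomized
parameter draws for the steady-state property, 100 randomized graphs
for serialization round-trips, and 500 randomized expression trees for
the parser-oracle comparison. The closed-form decay check runs at
solver tolerances 1e-9/1e-12 so that solver accuracy comfortably
supports the asserted 1e-6 agreement band on every grid point; all
other checks run at the default tolerances.

## Known limitations

* No symbolic simplification, differentiation or constant folding; the
  rendered equation is exactly the wiring.
* No unary minus (by design of the operator vocabulary); use the
  subtraction-fold idiom.
* The JSON format is this package's own documented schema
  (`format_version` 1.0); no claim of byte compatibility with any other
  tool's files is made.
* Plugin loading executes user code; the namespace is curated (decorator
  plus `math`) but this is not a security sandbox.
* Events, delays, stochastic simulation, parameter estimation and PDEs
  are out of scope.
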