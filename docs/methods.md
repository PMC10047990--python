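# Methods

## Model

The biocontinuum is modeled as a categorical distribution
`p = (p_1, …, p_n)` over `n ≥ 2` state types (the data model deliberately
does not distinguish "states of one organism's biocontinuum" from
"population types"; both are just types). The dynamics are the replicator
equation

    dp_i/dt = (f_i(p) − ⟨f(p)⟩) p_i,

with three fitness-landscape families: constant vectors `f_i = c_i`
(units 1/time), linear/payoff landscapes `f_i(p) = (A p)_i`, and arbitrary
registered functions `p ↦ f(p)`. Frequency-dependent fitness is always
evaluated at the normalized state; the unnormalized Lotka–Volterra form
`dP_i/dt = f_i P_i` is related by `p_i = P_i / Σ_j P_j` and the two routes
are required to agree (see Diagnostics).

Relative to a fixed target `q`, the observables are Shannon entropy
`S = −Σ p_i ln p_i`, the divergence `I(q,p) = Σ q_i ln(q_i/p_i)`, their
exact rates `Ṡ = −Σ (f_i − ⟨f⟩) p_i ln p_i` and `dI/dt = Σ f_i (p_i − q_i)`,
and the Lagrangian `dI/dt − I` whose time integral is the action. All
information quantities are in nats. The KL convention integrates over the
target `q` (the divergence's first argument), matching the defining
summation; for frequency-dependent fitness the chain rule still yields
`dI/dt = Σ f_i(p)(p_i − q_i)` exactly, since
`−Σ (ṗ_i/p_i) q_i = −Σ (f_i(p) − ⟨f(p)⟩) q_i`.

No variational optimization is performed on the action: the trajectory is
the one the replicator flow produces, and the action is a diagnostic
functional along it. Whether the action is extremal among perturbed paths is
not asserted; an exploratory test only confirms it is a genuine path
functional (perturbing the path moves its value).

## Geometry

The information geometry is implemented with the standard Amari
constructions, the concrete reading of the otherwise qualitative landscape
picture:

- simplex: Shahshahani/Fisher metric `g = diag(1/p_i)` on tangent vectors
  summing to zero, rejected at boundary points;
- Gaussian `(µ, σ)` manifold: `g = diag(1/σ², 2/σ²)`, with σ the standard
  deviation ("variance σ" in informal usage is read as a notational slip).
  The Fisher–Rao distance uses the Poincaré half-plane closed form
  `d = √2 · arccosh(1 + ((Δµ)²/2 + (Δσ)²)/(2 σ_a σ_b))`.

Natural-gradient descent iterates `x ← x − step · g(x)⁻¹ ∇V(x)` with
central-difference gradients (relative step `1e-6`), so arbitrary user
objectives are supported without symbolic derivatives. Simplex iterates are
retracted (clip to the probability floor, renormalize). A step failing to
decrease the objective is halved up to 30 times; if no decrease exists and
the gradient norm exceeds `1e-6` the flow raises a stall error, while a
vanishing gradient (below `1e-9`, or a sub-`1e-6` residual gradient whose
decrease is under round-off) terminates the flow as converged. The CLI's
geometry subcommand ships a deliberately simple illustrative objective — the
KL divergence from a fixed target — because no specific landscape surface is
canonical.

For symmetric payoff `A` the replicator flow is the Shahshahani
natural-gradient ascent of the potential `V(p) = ½ pᵀA p`;
`replicator_is_natural_gradient_check` verifies the monotone ascent of `V`
along simulated trajectories (per-step tolerance `1e-9`).

## Numerics

- Integrator: `scipy.integrate.solve_ivp` with the explicit Runge–Kutta
  DOP853 method, `rtol = 1e-8`, `atol = 1e-10` by default, dense output
  sampled on a uniform grid (default 201 points). Each reported state is
  clipped to `[0, 1]` and renormalized; validation forgives deviations at
  round-off level only (entries ≥ −1e-12, sums within 1e-6) and is exactly
  idempotent.
- Simplex boundary: probabilities exactly 0 are legal states; logarithms
  evaluate `max(p_i, prob_floor)` with `prob_floor = 1e-12`, and entropy
  sums use the limit `0 ln 0 = 0`. `I(q,p)` is `+inf` (optionally an error)
  when `q` has mass where `p` has fallen below the floor.
- Lotka–Volterra integration works in `log P_i` (shifted by `logsumexp`
  before normalization), which is exact for the normalized state and immune
  to overflow on long horizons — equivalent to rescaling counts by their
  sum, which leaves `p` unchanged.
- Constant-fitness closed form `p_i(t) ∝ p_i(0) e^{f_i t}` is computed in
  log space for the same reason.
- Action quadrature: composite trapezoid on the trajectory grid (order 2); a
  2× coarsening check warns when the value shifts by more than 1e-4 relative.
- Equilibria: all vertices always; for payoff landscapes the interior
  candidate solves the (n+1)-dimensional linear system `(A p)_i = φ`,
  `Σ p_i = 1`, kept when strictly positive; rank-deficient systems are
  flagged singular, all-equal constant fitness is flagged neutral. Interior
  search for custom fitness is out of scope. Fitness ties within 1e-12 are
  treated as neutral in argmax-based diagnostics.
- Lyapunov analysis: per-step increase tolerance 1e-7 nats, whole-trajectory
  conservation tolerance 1e-6 nats.

## Study conditions and diagnostics

The seeded scenario generator defines the test conditions: `p0` (and
optional `q`) from a flat Dirichlet, constant fitness with standard-normal
entries, payoff matrices symmetrized `(A+Aᵀ)/2` or antisymmetrized
`(A−Aᵀ)/2` from standard-normal draws, default horizon `t ∈ [0, 5]` with
201 output points. These are generic, O(1)-scale landscapes; identical seeds
reproduce identical scenarios bit-for-bit.

Acceptance-style diagnostics (also recomputed by `scripts/acceptance.py`)
and the problem sizes used: closed-form agreement on 501 points over
`t ∈ [0, 10]` (sup-norm < 1e-6); probability-mass conservation on 50 seeded
scenarios (< 1e-8); finite-difference consistency of both rate formulas at
`Δt = 1e-3` vs `5e-4` (max error < 1e-5, error ratio ≈ 4); Fisher's
fundamental theorem at Δt = 1e-3 over `t ∈ [0, 5]` (< 1e-5); Lyapunov
monotone descent toward a dominant vertex and conservation within 1e-6 on
rock–paper–scissors over `t ∈ [0, 50]`; Lotka–Volterra/replicator sup-gap
< 1e-6 on 6 seeded scenarios; exact zero action on stationary `p = q`
trajectories and trapezoid refinement ratio ≈ 4 against a 4097-point
reference; metric/KL second-order agreement within 1% at 200 seeded points
with `|δ| = 1e-3` (simplex points sampled well interior, since the cubic
remainder scales like `|δ|/min p_i`); Fisher–Rao distances `(0,1)→(0,e)` and
`(0,1)→(1,1)` against `√2` and `√2 ln 2` and against an independent
geodesic boundary-value-problem oracle (1e-6); natural-gradient convergence
to KL targets within 1e-4; and potential ascent on 100 seeded symmetric
payoffs (per-step tolerance 1e-9).

## What the synthetic scenarios do and do not show

The generator emulates generic smooth fitness landscapes at unit scale with
exact simplex-valued initial conditions. It does not emulate measurement
noise, stochastic drift at finite population size (Moran/Wright–Fisher),
mutation–selection balance, time-varying targets `q(t)`, or landscapes with
near-degenerate fitness gaps. Passing diagnostics therefore certify the
deterministic mathematics and its numerics, not robustness of inference on
noisy biological data.

## Known limitations

- Continuous (infinite-type) state distributions are out of scope; the
  simplex is finite-dimensional.
- `I(q,p)` diverges when the flow drives `p` off the support of `q`
  (e.g. the target puts mass on a type that selection eliminates); the
  probability floor keeps observables finite only down to `1e-12`.
- Interior equilibria are found only for linear fitness; faces are not
  searched exhaustively.
- Stiff custom fitness functions may need smaller `max_step`/tolerances;
  defaults are tuned for O(1) fitness scales.
- The error-function/control-theoretic reading of fitness is left as a
  fitness-model extension point (register a custom function); no such
  machinery is built in.
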