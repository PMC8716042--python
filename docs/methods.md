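# Methods

## The model

A long-term dyadic relationship is summarized by a scalar *feeling* state
`x(t) >= 0` (marital quality / relationship satisfaction) obeying

    dx/dt = -r x + a1 c1 + a2 c2,

where `r > 0` is a natural decay rate (feelings erode without maintenance),
`c_i(t) >= 0` is partner *i*'s effort, and `a_i >= 0` converts effort into
feeling. Each partner maximizes a discounted well-being integral

    W_i = ∫_0^∞ e^{-rho_i t} [ U_i(x(t)) - D_i(c_i(t)) ] dt,

with `U_i` increasing, strictly concave and satiating (default
`U(x) = alpha ln(x+1)`, alpha = 5), and `D_i` strictly convex with an
interior minimum at a *preferred effort* `c_i* >= 0` (default
`D(c) = w/2 (c - c*)^2`, w = 1, c* = 0.2). Effort beyond the preferred level
is increasingly painful; disutility depends on own effort only.

With two partners this is a nonzero-sum differential game; the solution
concept is the *stationary feedback Nash equilibrium*: a pair of maps
`S_i(x)` such that each partner's feedback rule is optimal against the
other's. The associated value functions `v_i(x)` solve a coupled stationary
HJB system. With one partner (the couple treated as a unit) the same
machinery reduces to a standard infinite-horizon optimal control problem.

The benchmark parameter set used throughout (and bundled as
`benchmark_problem`) is `r = 2`, `rho = 0.1`, `a = 1`, alpha = 5, `c* = 0.2`,
`w = 1`, domain `x ∈ [0, 5]`. Its closed-form 1D stationary point is
`(x̄, c̄) = (0.7719, 1.5437)`.

## Discretization

The HJB system is discretized semi-Lagrangianly with time step `h`
(default 0.01): at a node `y`,

    v_i(y) = max_{c ∈ [0, c_max]} h (U_i(y) - D_i(c))
             + (1 - rho_i h) v_i( y + h f(y, c, S_j(y)) ),

with the continuation value at the Euler image evaluated off-node by radial
basis function (RBF) collocation over `Q` scattered nodes (default 41,
uniform; Halton available). The kernel is Gaussian
`phi(r) = exp(-eps r^2)` with shape `eps = 1/(2 * mean spacing)`, augmented
with a linear polynomial tail so constants and affine functions are
reproduced exactly, plus a small ridge on the collocation diagonal. Euler
images falling outside the state domain are clamped to it before
evaluation; kernel extrapolation is unstable and the images leave the
domain only marginally at the boundary.

The default `h = 0.01` is chosen so that the closed-loop linearization rate
near the benchmark equilibrium (~2.36 per unit time) gives per-period
dynamics consistent with the recovery horizons the simulations report;
`h` must also satisfy `1 - r h > 0` and `1 - rho_i h > 0`.

## The double loop

The solver iterates two nested fixed points:

* **Inner (game) iteration.** At every node simultaneously, damped
  best-response sweeps (damping 0.5) until the per-node effort profile
  changes by less than `game_tol` (1e-8). The scalar maximization is a
  501-point coarse grid scan over `[0, c_max]` followed by golden-section
  refinement (bracket tolerance 1e-9, ties toward the smallest effort) and
  a final Newton polish on the analytic first-order condition
  `-D'(c) + (1 - rho h) a RBF[V]'(y^#) = 0`. The polish matters: a purely
  value-comparison search resolves the flat maximum only to about
  sqrt(machine epsilon), which is too coarse for the strategy tolerance
  below. Repeated sweeps inside the inner loop reuse the previous
  maximizer and apply the Newton continuation only; the full scan runs
  once per outer pass, and the final Bellman-residual check (below) verifies
  global optimality of the converged strategies.

* **Outer (value) iteration.** Given converged node strategies, node values
  are updated to the exact fixed point of the resulting linear
  (policy-evaluation) system `v = h pi + (1 - rho h) W v`, where `W` maps
  node values to interpolated continuation values at the closed-loop Euler
  images. A single Bellman sweep per outer pass would contract only at
  `1 - rho h = 0.999` per pass and need ~1e4 passes; the linear solve
  removes that bottleneck. Strategy and value updates are relaxed with a
  factor that starts at 0.5 and anneals (x0.7, floor 0.02) whenever the
  strategy change stops decreasing — this quenches a small limit cycle that
  interpolation wiggle otherwise sustains near the fixed point. The loop
  stops when the value change falls below 1e-6 and the strategy change
  below 1e-8 in sup norm.

Values are initialized at `U_i(y)/rho_i` (the value of a frozen feeling at
zero effort cost) and strategies at the preferred efforts. Divergence
(value norm beyond 1e6 x its initial scale) raises. If a maximizer lands on
the control bound `c_max` (default 5), the problem is re-solved once with
the bound doubled.

### Numerical stability of the collocation weights

With the flat Gaussian kernel at `eps = 1/(2 spacing)` the exact
(ridge-free) cardinal functions are violently oscillatory (sup-norm of the
interpolation weight matrix ~1e2 on the benchmark node set). Because the
per-period discount `1 - rho h` is within 1e-3 of unity, the policy
evaluation amplifies node-value noise by roughly three orders of magnitude,
and the outer loop then sustains visible strategy oscillation at the domain
boundary. The solver therefore uses a ridge of 1e-6 in its kernel
configuration (the generic interpolation default is 1e-12), which brings
the weight-matrix norm down to ~2.5 at an interpolation error of ~1.5e-3 on
value-scale functions. On the benchmark this keeps the solved steady state
within 0.2% of the closed form. The price is smoothing of *derivatives* of
the solved curves near high-curvature regions; diagnostics that need the
local feedback slope (e.g. comparing with the stable-manifold slope at the
equilibrium) should be run at a finer resolution (Q = 61, ridge 1e-7
converges in seconds and matches the eigenvector slope to ~0.1%).

## Trajectories, shocks, recovery

Closed-loop runs iterate `c_{i,k} = S_i(x_k)`,
`x_{k+1} = x_k + h f(x_k, c_{1,k}, c_{2,k})`, with strategies evaluated
off-node through their RBF interpolants. Shock-perturbed runs add a sparse
schedule `sigma_{k+1}` after each Euler update; partners respond to the
observed (perturbed) state in the following period. A state leaving the
domain is clamped and flagged; a dip below the viability threshold `x_min`
(default 0) sets a breakdown flag but never halts the run.

The bundled stress fixture places 12 consecutive negative shocks starting
at period 85, linearly ramped from -0.15 to -0.05 (the source text gives
the endpoints and calls the shocks "decreasing" without fixing the order;
the ramp of decreasing magnitude is adopted). Shock indices are simulation
periods; the narrative identification of a period with a month is treated
as narrative only — recovery counts in periods are `h`-dependent, and `h`
is a configuration knob.

Discounted well-being along a path is `h * sum_k e^{-rho t_k} (U - D)`.
Recovery time after a shock is the number of periods from the first shock
until the feeling first regains 95% of a given baseline (0 if it never
dips below; flagged if it never recovers within the horizon).

## Saddle-path oracle (1D)

For the single-partner problem, the maximum principle yields the planar
system

    dx/dt = -r x + a c
    dc/dt = (1/D''(c)) [ (r + rho) D'(c) - a U'(x) ].

Its unique positive equilibrium solves `x̄ = a c̄ / r` together with
`(r + rho) D'(c̄) = a U'(x̄)` — one quadratic in `c̄` for the log/quadratic
family, safeguarded Newton otherwise. The Jacobian
`[[-r, a], [-a U''/D'', r + rho]]` always has negative determinant under
the model's shape assumptions, so the equilibrium is a saddle; the optimal
path is its stable manifold. A shooting routine bisects the initial effort
`c(0)` until the RK4 path (step 1e-3, horizon 10 time units) neither
escapes upward (effort blow-up) nor crashes downward. Two care points:
(i) the under/overshoot classification must trigger *before* the state
leaves the physically meaningful region — for the log family the costate
term is singular at `x = -1` and flips sign beyond it, making the final
point of a crashed path uninformative — so crash detection uses an effort
floor and a feeling floor above the singularity; (ii) the bisected `c(0)`
is accurate to 1e-6 only, so the raw path eventually leaves the saddle
along the unstable direction; the returned path is cut at its closest
approach to the equilibrium.

A switch (`use_u_prime=False`) evaluates the costate term with `U(x)` in
place of `U'(x)`. The derivative form is the default: it is what the
costate derivation produces, and it is the only form that reproduces the
benchmark equilibrium `(0.77, 1.55)`.

This module is deliberately independent of the HJB solver (different
discretization, different optimization) and serves as its oracle: the 1D
closed-loop trajectory from the solved feedback map tracks the shooting
path within 2% of the feeling scale, and the solved initial effort at
`x = 3` matches the shooting value ~1.087 within 1%.

## Known discrepancy: the homogamous 2D equilibrium level

The recovery analysis published for the benchmark inputs implies an
equilibrium feeling of about 1.59 for the homogamous couple (`a1 = a2 = 1`,
a -0.2 shock said to be 12.6% of the equilibrium). The feedback Nash fixed
point this solver finds is `x̄ ≈ 1.193`. The solver's answer is internally
verified: the Bellman residual at the fixed point is ~1e-8, the solution is
reached from widely different initializations, and it satisfies the
analytic steady-state conditions (first-order condition `D'(c̄) = a v'(x̄)`
with the envelope relation `v' = U'/(rho + r - a S')`) to 0.2%. Reaching
1.59 would require `v' = 1.5 U'/(r + rho)`, i.e. a *positive*
opponent-strategy slope around +0.7 — contradicting the decreasing feedback
maps the same analysis reports. The corresponding check is kept in the test
suite at its stated tolerance and fails; all orderings and ratios of the
recovery analysis (equilibrium feeling increasing in `a2`, relative shock
size decreasing, recovery periods decreasing) do hold.

## What the defaults do and do not show

All experiments are deterministic — there is no randomness anywhere in the
pipeline (Halton nodes are a deterministic sequence), and re-runs are
bitwise identical. The synthetic couples are fully described by the model:
real longitudinal marital data would add measurement noise, heterogeneity
in preferences beyond effort efficiency, multi-dimensional emotional
states, and stochastic life events, none of which are modeled here.
Passing tests show that the solver reproduces the mathematical objects of
the model (equilibria, saddle paths, comparative statics), not that the
model describes any particular couple.

## Problem sizes used by the test suite and the acceptance script

The default solves use Q = 41 nodes and h = 0.01; a 1D solve takes under a
second and 2D solves seconds to about a minute (the strongly coupled
high-efficiency couples, `a2 >= 1.5`, need the most outer passes).
Recovery experiments simulate 3000 periods; well-being consistency checks
integrate 12000 periods (120 time units, truncation error well under the
2% comparison tolerance). The itch-fixture checks observe 450 periods so
the perturbed path has re-joined the baseline within 1%.
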