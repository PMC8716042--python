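"""Feedback Nash equilibrium solver for the discrete HJB system.

The continuous coupled HJB system is discretized semi-Lagrangianly: with
time step ``h`` the value of partner ``i`` at a node ``y`` satisfies

    v_i(y) = max_{c in [0, c_max]}  h (U_i(y) - D_i(c))
             + (1 - rho_i h) * RBF[V_i](y + h f(y, c, S_j(y)))

where the opponent plays the current strategy iterate and the continuation
value at the (off-node) Euler image is evaluated by RBF interpolation.  The
scheme is solved by a double loop:

* inner *game iteration*: at every node, damped best-response sweeps until
  the per-node effort profile is a fixed point (a Nash equilibrium of the
  one-shot node game);
* outer *value iteration*: given converged node strategies, node values are
  updated to the fixed point of the resulting linear (policy-evaluation)
  system, the value interpolants are refit, and the loop repeats until
  value and strategy sup-norm changes fall below tolerance.

The scalar maximization is a coarse grid scan followed by golden-section
refinement, ties broken toward the smallest effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import CoupleProblem
from .rbf import (KernelConfig, NodeSet, RBFInterpolant, eval_rbf,
                  eval_rbf_deriv, fit_rbf, interpolation_matrix)

__all__ = [
    "SolverConfig",
    "ConvergenceReport",
    "FeedbackSolution",
    "best_response",
    "game_iterate_node",
    "solve_hjb",
    "bellman_residual",
    "steady_state",
]

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden ratio conjugate


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the double-loop scheme.

    ``h`` is the semi-Lagrangian time step (time units); it must satisfy
    ``1 - rho_i h > 0`` and ``1 - r h > 0``.  Controls are truncated to
    ``[0, c_max]`` (the maximizer is asserted to be interior; see
    :func:`solve_hjb`).  ``n_control`` is the coarse-grid resolution and
    ``opt_tol`` the golden-section bracket tolerance.  ``damping`` weights
    the best-response update in the inner game iteration.
    """

    h: float = 0.01
    c_max: float = 5.0
    n_control: int = 501
    opt_tol: float = 1e-9
    value_tol: float = 1e-6
    strategy_tol: float = 1e-8
    game_tol: float = 1e-8
    damping: float = 0.5
    max_outer: int = 2500
    max_inner: int = 200
    Q: int = 41
    node_scheme: str = "uniform"
    # a slightly stronger ridge than the interpolation default keeps the
    # collocation weights tame inside the value loop (wild cardinal
    # functions otherwise amplify node-value noise through the near-unit
    # discount factor)
    kernel: KernelConfig = field(default_factory=lambda: KernelConfig(ridge=1e-6))

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError("h must be positive")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")
        for name in ("opt_tol", "value_tol", "strategy_tol", "game_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def validate_for(self, problem: CoupleProblem) -> None:
        if not 1.0 - problem.r * self.h > 0:
            raise ValueError("time step too large: 1 - r h must be positive")
        for p in problem.partners:
            if not 1.0 - p.rho * self.h > 0:
                raise ValueError("time step too large: 1 - rho h must be positive")

    def make_nodes(self, problem: CoupleProblem) -> NodeSet:
        if self.node_scheme == "uniform":
            return NodeSet.uniform(problem.x_lo, problem.x_hi, self.Q)
        if self.node_scheme == "halton":
            return NodeSet.halton(problem.x_lo, problem.x_hi, self.Q)
        raise ValueError(f"unknown node scheme {self.node_scheme!r}")


@dataclass
class ConvergenceReport:
    outer_iterations: int = 0
    max_inner_iterations: int = 0
    value_change: float = np.inf
    strategy_change: float = np.inf
    bellman_residual: float = np.inf
    value_change_history: list = field(default_factory=list)
    converged: bool = False
    inner_converged: bool = True


@dataclass
class FeedbackSolution:
    """Per-partner value and strategy interpolants plus node tables."""

    problem: CoupleProblem
    config: SolverConfig
    nodes: NodeSet
    values: np.ndarray     # (n_players, Q) node values
    strategies: np.ndarray  # (n_players, Q) node efforts
    value_interp: tuple[RBFInterpolant, ...]
    strategy_interp: tuple[RBFInterpolant, ...]
    report: ConvergenceReport

    def value(self, i: int, x):
        return eval_rbf(self.value_interp[i], x)

    def strategy(self, i: int, x):
        return eval_rbf(self.strategy_interp[i], x)

    def strategies_at(self, x) -> np.ndarray:
        return np.array([self.strategy(i, x) for i in range(self.problem.n_players)])


# ---------------------------------------------------------------------------
# scalar best response
# ---------------------------------------------------------------------------

def _objective_batch(y, c_grid, opp_drift, partner, v_interp, problem, config):
    """Semi-Lagrangian objective on a batch of nodes x control grid.

    ``y``: (n,) nodes; ``c_grid``: (n, m) candidate own efforts;
    ``opp_drift``: (n,) drift contribution of everything except own effort.
    Returns (n, m) objective values.
    """
    h = config.h
    y = np.atleast_1d(np.asarray(y, dtype=float))
    y_next = y[:, None] + h * (opp_drift[:, None] + partner.a * c_grid)
    cont = eval_rbf(v_interp, np.clip(y_next, problem.x_lo, problem.x_hi))
    obj = h * (partner.utility(y)[:, None] - partner.cost(c_grid)) \
        + (1.0 - partner.rho * h) * cont
    if not np.all(np.isfinite(obj)):
        raise FloatingPointError("non-finite semi-Lagrangian objective")
    return obj


def _best_response_batch(y, opp_drift, partner, v_interp, problem, config,
                         warm=None):
    """Vectorized argmax over own effort at each node: coarse grid scan then
    golden-section refinement; ties go to the smallest effort.

    With ``warm`` (previous efforts) the scan is skipped and the maximizer
    is continued by Newton steps on the first-order condition alone -- used
    for the repeated sweeps inside the game iteration, where the maximizer
    moves only slightly; the full scan still runs once per outer pass.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n = y.size
    if warm is not None:
        return _newton_polish(y, np.asarray(warm, dtype=float).copy(),
                              opp_drift, partner, v_interp, problem, config,
                              n_iter=8)
    grid = np.linspace(0.0, config.c_max, config.n_control)
    obj = _objective_batch(y, np.broadcast_to(grid, (n, grid.size)),
                           opp_drift, partner, v_interp, problem, config)
    k = np.argmax(obj, axis=1)  # first max -> smallest effort on ties
    dc = grid[1] - grid[0]
    lo = np.maximum(grid[k] - dc, 0.0)
    hi = np.minimum(grid[k] + dc, config.c_max)
    # golden-section on [lo, hi] per node, all nodes advanced in lockstep
    x1 = hi - _INVPHI * (hi - lo)
    x2 = lo + _INVPHI * (hi - lo)
    f1 = _objective_batch(y, x1[:, None], opp_drift, partner, v_interp,
                          problem, config)[:, 0]
    f2 = _objective_batch(y, x2[:, None], opp_drift, partner, v_interp,
                          problem, config)[:, 0]
    span = float(np.max(hi - lo)) if n else 0.0
    while span > config.opt_tol:
        take1 = f1 >= f2  # maximum in the left interval; ties -> smaller c
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
        new_x1 = hi - _INVPHI * (hi - lo)
        new_x2 = lo + _INVPHI * (hi - lo)
        fresh_x = np.where(take1, new_x1, new_x2)
        fresh_f = _objective_batch(y, fresh_x[:, None], opp_drift, partner,
                                   v_interp, problem, config)[:, 0]
        x1_old, f1_old = x1, f1
        x2_old, f2_old = x2, f2
        x1 = np.where(take1, new_x1, x2_old)
        f1 = np.where(take1, fresh_f, f2_old)
        x2 = np.where(take1, x1_old, new_x2)
        f2 = np.where(take1, f1_old, fresh_f)
        span *= _INVPHI
    mid = 0.5 * (lo + hi)
    c = np.clip(mid, 0.0, config.c_max)
    return _newton_polish(y, c, opp_drift, partner, v_interp, problem, config)


def _newton_polish(y, c, opp_drift, partner, v_interp, problem, config,
                   n_iter: int = 4):
    """Sharpen interior maximizers on the first-order condition

        -D'(c) + (1 - rho h) a * v'(y + h f) = 0

    using the analytic kernel derivative.  Golden-section alone resolves the
    flat maximum only to ~sqrt(machine eps); the polish removes that noise
    floor so the outer loop can meet tight strategy tolerances.  Boundary
    maximizers and clamped Euler images are left untouched.
    """
    if partner.a == 0.0:
        return c
    h = config.h
    beta = 1.0 - partner.rho * h
    cell = config.c_max / (config.n_control - 1)
    lo_ok = c > 1e-12
    hi_ok = c < config.c_max - 1e-12
    for _ in range(n_iter):
        y_next = y + h * (opp_drift + partner.a * c)
        interior = lo_ok & hi_ok & (y_next > problem.x_lo) & (y_next < problem.x_hi)
        if not np.any(interior):
            break
        g1 = eval_rbf_deriv(v_interp, y_next, order=1)
        g2 = eval_rbf_deriv(v_interp, y_next, order=2)
        F = -partner.cost.prime(c) + beta * partner.a * g1
        dF = -partner.cost.second(c) + beta * partner.a**2 * h * g2
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(dF < 0, -F / dF, 0.0)
        step = np.clip(step, -cell, cell)  # stay inside the bracketed cell
        c = np.where(interior, np.clip(c + step, 0.0, config.c_max), c)
    return c


def best_response(y: float, i: int, opponent_effort: float,
                  v_i: RBFInterpolant, problem: CoupleProblem,
                  config: SolverConfig) -> float:
    """Best effort of partner ``i`` at node ``y`` given the opponent's effort.

    Maximizes ``h (U_i(y) - D_i(c)) + (1 - rho_i h) v_i(y + h f(y, .))``
    over ``c in [0, c_max]`` with the Euler image clamped to the domain.
    """
    if opponent_effort is not None and opponent_effort < 0:
        raise ValueError("opponent effort must be non-negative")
    partner = problem.partners[i]
    opp = 0.0
    if problem.n_players == 2:
        j = 1 - i
        opp = problem.partners[j].a * float(opponent_effort or 0.0)
    opp_drift = np.array([-problem.r * y + opp])
    c = _best_response_batch(np.array([y]), opp_drift, partner, v_i,
                             problem, config)
    return float(c[0])


def game_iterate_node(y: float, initial_efforts, value_interps,
                      problem: CoupleProblem, config: SolverConfig):
    """Damped best-response fixed point of the one-shot game at node ``y``.

    Returns ``(efforts, n_iterations, converged)``.  A single-partner
    problem needs one best-response call; with two partners, sweeps repeat
    until the effort change drops below ``game_tol``.
    """
    efforts = np.asarray(initial_efforts, dtype=float).copy()
    if np.any(efforts < 0) or np.any(efforts > config.c_max):
        raise ValueError("initial efforts must lie within [0, c_max]")
    if problem.n_players == 1:
        c = best_response(y, 0, None, value_interps[0], problem, config)
        return np.array([c]), 1, True
    for it in range(1, config.max_inner + 1):
        new = efforts.copy()
        for i in range(2):
            br = best_response(y, i, new[1 - i], value_interps[i], problem, config)
            new[i] = (1.0 - config.damping) * new[i] + config.damping * br
        change = float(np.max(np.abs(new - efforts)))
        efforts = new
        if change < config.game_tol:
            return efforts, it, True
    return efforts, config.max_inner, False


# ---------------------------------------------------------------------------
# the double loop
# ---------------------------------------------------------------------------

def _game_iterate_all_nodes(y, strategies, value_interps, problem, config):
    """Damped best-response sweeps at every node simultaneously."""
    n_players = problem.n_players
    S = strategies.copy()
    base_drift = -problem.r * y
    if n_players == 1:
        S[0] = _best_response_batch(y, base_drift, problem.partners[0],
                                    value_interps[0], problem, config)
        return S, 1, True
    for it in range(1, config.max_inner + 1):
        new = S.copy()
        for i in range(2):
            j = 1 - i
            opp_drift = base_drift + problem.partners[j].a * new[j]
            br = _best_response_batch(y, opp_drift, problem.partners[i],
                                      value_interps[i], problem, config,
                                      warm=None if it == 1 else new[i])
            new[i] = (1.0 - config.damping) * new[i] + config.damping * br
        change = float(np.max(np.abs(new - S)))
        S = new
        if change < config.game_tol:
            return S, it, True
    return S, config.max_inner, False


def _policy_values(y, S, problem, config, nodes):
    """Node values under frozen strategies: solve the linear fixed point

    v_i = h (U_i - D_i(S_i)) + (1 - rho_i h) W v_i,

    where ``W`` maps node values to interpolated continuation values at the
    closed-loop Euler images.  This evaluates the current strategy profile
    exactly rather than by repeated Bellman sweeps.
    """
    h = config.h
    Q = nodes.Q
    drift = -problem.r * y
    for i, p in enumerate(problem.partners):
        drift = drift + p.a * S[i]
    y_next = np.clip(y + h * drift, problem.x_lo, problem.x_hi)
    W = interpolation_matrix(nodes, config.kernel, y_next,
                             problem.x_lo, problem.x_hi)
    values = np.empty((problem.n_players, Q))
    for i, p in enumerate(problem.partners):
        payoff = h * (p.utility(y) - p.cost(S[i]))
        beta = 1.0 - p.rho * h
        values[i] = np.linalg.solve(np.eye(Q) - beta * W, payoff)
    return values


def solve_hjb(problem: CoupleProblem, config: SolverConfig | None = None) -> FeedbackSolution:
    """Run the value/game double loop to a stationary feedback equilibrium.

    Node values start at ``U_i(y) / rho_i`` (the value of a frozen feeling
    at zero effort cost) and strategies at the preferred efforts.  Each
    outer pass refits the value interpolants, converges the per-node game
    iteration, and updates node values from the maximized right-hand side of
    the discrete HJB under the new strategies.  If the maximizer hits the
    control bound the problem is re-solved once with ``c_max`` doubled.
    """
    config = config or SolverConfig()
    config.validate_for(problem)
    nodes = config.make_nodes(problem)
    y = nodes.points
    n_players = problem.n_players

    values = np.stack([p.utility(y) / p.rho for p in problem.partners])
    strategies = np.stack([np.full(nodes.Q, p.cost.cstar) for p in problem.partners])
    value_scale = max(float(np.max(np.abs(values))), 1.0)

    report = ConvergenceReport()
    # outer relaxation: start at the configured damping and anneal it when
    # the strategy change stops decreasing, which quenches the small limit
    # cycle that interpolation wiggle would otherwise sustain near the
    # fixed point
    relax = config.damping
    prev_ds = np.inf
    for outer in range(1, config.max_outer + 1):
        v_interps = [fit_rbf(nodes, values[i], config.kernel,
                             x_lo=problem.x_lo, x_hi=problem.x_hi)
                     for i in range(n_players)]
        game_S, inner_its, inner_ok = _game_iterate_all_nodes(
            y, strategies, v_interps, problem, config)
        new_S = (1.0 - relax) * strategies + relax * game_S
        new_values = (1.0 - relax) * values \
            + relax * _policy_values(y, new_S, problem, config, nodes)

        dv = float(np.max(np.abs(new_values - values)))
        ds = float(np.max(np.abs(new_S - strategies)))
        values, strategies = new_values, new_S
        if ds > prev_ds and outer > 20:
            relax = max(0.7 * relax, 0.02)
        prev_ds = ds
        report.outer_iterations = outer
        report.max_inner_iterations = max(report.max_inner_iterations, inner_its)
        report.inner_converged = report.inner_converged and inner_ok
        report.value_change = dv
        report.strategy_change = ds
        report.value_change_history.append(dv)
        if float(np.max(np.abs(values))) > 1e6 * value_scale:
            raise FloatingPointError(
                f"value iteration diverging at outer pass {outer}: "
                f"|v| grew beyond 1e6 x initial scale ({value_scale:g})"
            )
        if dv < config.value_tol and ds < config.strategy_tol:
            report.converged = True
            break

    if np.any(strategies > config.c_max - 10 * config.opt_tol):
        # maximizer at the control bound: re-solve with a doubled bound
        wider = replace(config, c_max=2.0 * config.c_max)
        return solve_hjb(problem, wider)

    v_interps = tuple(fit_rbf(nodes, values[i], config.kernel,
                              x_lo=problem.x_lo, x_hi=problem.x_hi)
                      for i in range(n_players))
    s_interps = tuple(fit_rbf(nodes, strategies[i], config.kernel,
                              x_lo=problem.x_lo, x_hi=problem.x_hi)
                      for i in range(n_players))
    solution = FeedbackSolution(problem=problem, config=config, nodes=nodes,
                                values=values, strategies=strategies,
                                value_interp=v_interps,
                                strategy_interp=s_interps, report=report)
    report.bellman_residual = bellman_residual(solution, problem, config)
    return solution


def bellman_residual(solution: FeedbackSolution, problem: CoupleProblem,
                     config: SolverConfig) -> float:
    """Sup-norm discrepancy between stored node values and the maximized
    right-hand side of the discrete HJB at every node."""
    y = solution.nodes.points
    base_drift = -problem.r * y
    resid = 0.0
    for i, p in enumerate(problem.partners):
        opp_drift = base_drift.copy()
        if problem.n_players == 2:
            j = 1 - i
            opp_drift = opp_drift + problem.partners[j].a * solution.strategies[j]
        c = _best_response_batch(y, opp_drift, p, solution.value_interp[i],
                                 problem, config)
        obj = _objective_batch(y, c[:, None], opp_drift, p,
                               solution.value_interp[i], problem, config)[:, 0]
        resid = max(resid, float(np.max(np.abs(obj - solution.values[i]))))
    return resid


def steady_state(solution: FeedbackSolution, problem: CoupleProblem):
    """Stationary feeling of the closed-loop dynamics and the efforts there.

    Bisects the closed-loop drift ``-r x + sum_i a_i S_i(x)`` on the state
    domain to 1e-8.  Raises if the drift does not change sign (unless it
    vanishes at a boundary, e.g. pure decay with zero efficiencies).
    """
    def g(x):
        total = -problem.r * x
        for i, p in enumerate(problem.partners):
            total += p.a * solution.strategy(i, x)
        return total

    lo, hi = problem.x_lo, problem.x_hi
    g_lo, g_hi = g(lo), g(hi)
    if g_lo == 0.0:
        xbar = lo
    elif g_hi == 0.0:
        xbar = hi
    elif g_lo * g_hi > 0:
        raise ValueError("no interior stationary state: closed-loop drift "
                         "does not change sign on the domain")
    else:
        while hi - lo > 1e-8:
            mid = 0.5 * (lo + hi)
            if g(lo) * g(mid) <= 0:
                hi = mid
            else:
                lo = mid
        xbar = 0.5 * (lo + hi)
    efforts = np.array([solution.strategy(i, xbar)
                        for i in range(problem.n_players)])
    return float(xbar), efforts
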