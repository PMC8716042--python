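"""HJB double-loop solver: best responses, node games, full solves."""

import numpy as np
import pytest

from dyadgame import (CoupleProblem, EffortCost, KernelConfig, NodeSet,
                      PartnerSpec, SolverConfig, UtilityCurve,
                      bellman_residual, best_response, equilibrium_closed_form,
                      fit_rbf, game_iterate_node, rk4_integrate, simulate,
                      shoot_initial_effort, solve_hjb, steady_state,
                      benchmark_problem)
from dyadgame.solver import FeedbackSolution


def _linear_interp(slope, cfg, problem):
    nodes = cfg.make_nodes(problem)
    return fit_rbf(nodes, slope * nodes.points, cfg.kernel,
                   x_lo=problem.x_lo, x_hi=problem.x_hi)


class TestBestResponse:
    def test_zero_efficiency_plays_preferred_effort(self, config):
        prob = benchmark_problem(2, a1=1.0, a2=0.0)
        v = _linear_interp(1.0, config, prob)
        c = best_response(2.5, 1, 1.0, v, prob, config)
        assert c == pytest.approx(0.2, abs=1e-6)

    def test_constant_value_plays_preferred_effort(self, config):
        prob = benchmark_problem(1)
        v = _linear_interp(0.0, config, prob)
        assert best_response(2.5, 0, None, v, prob, config) == pytest.approx(
            0.2, abs=1e-6)

    def test_linear_value_first_order_condition(self, config):
        # slope kappa = 1: c = c* + a (1 - rho h) kappa = 1.199
        prob = benchmark_problem(1)
        v = _linear_interp(1.0, config, prob)
        c = best_response(2.5, 0, None, v, prob, config)
        assert c == pytest.approx(0.2 + 1.0 * (1 - 0.1 * config.h), abs=1e-4)

    def test_negative_opponent_effort_rejected(self, config):
        prob = benchmark_problem(2)
        v = _linear_interp(1.0, config, prob)
        with pytest.raises(ValueError):
            best_response(2.5, 0, -1.0, v, prob, config)


class TestGameIterateNode:
    def test_single_player_fixed_point_in_one_call(self, config):
        prob = benchmark_problem(1)
        v = [_linear_interp(1.0, config, prob)]
        efforts, its, ok = game_iterate_node(2.5, [0.2], v, prob, config)
        assert ok and its == 1
        assert efforts[0] == pytest.approx(1.199, abs=1e-3)

    def test_zero_efficiency_partner_decouples(self, config):
        prob = benchmark_problem(2, a1=1.0, a2=0.0)
        vs = [_linear_interp(1.0, config, prob)] * 2
        efforts, _, ok = game_iterate_node(2.5, [0.2, 0.2], vs, prob, config)
        assert ok
        assert efforts[1] == pytest.approx(0.2, abs=1e-6)

    def test_symmetric_partners_equal_efforts(self, config):
        prob = benchmark_problem(2, a1=1.0, a2=1.0)
        vs = [_linear_interp(1.0, config, prob)] * 2
        efforts, _, ok = game_iterate_node(2.5, [0.2, 0.2], vs, prob, config)
        assert ok
        assert efforts[0] == pytest.approx(efforts[1], abs=1e-8)

    def test_out_of_bounds_initial_efforts_rejected(self, config):
        prob = benchmark_problem(2)
        vs = [_linear_interp(1.0, config, prob)] * 2
        with pytest.raises(ValueError):
            game_iterate_node(2.5, [-0.5, 0.2], vs, prob, config)


class TestSolve1D:
    def test_converged_with_small_residuals(self, solution_1d, config):
        rep = solution_1d.report
        assert rep.converged
        assert rep.value_change < config.value_tol
        assert rep.strategy_change < config.strategy_tol
        assert np.isfinite(rep.bellman_residual)

    def test_initial_effort_matches_benchmark(self, solution_1d):
        assert solution_1d.strategy(0, 3.0) == pytest.approx(1.087, rel=0.02)

    def test_steady_state_matches_closed_form(self, solution_1d):
        prob = solution_1d.problem
        xbar, cbar = steady_state(solution_1d, prob)
        eq = equilibrium_closed_form(prob.partners[0], prob.r)
        assert xbar == pytest.approx(eq.x, rel=0.02)
        assert cbar[0] == pytest.approx(eq.c, rel=0.02)

    def test_effort_gap_everywhere(self, solution_1d):
        assert np.all(solution_1d.strategies[0] >= 0.2)

    def test_monotone_feedback_and_value(self, solution_1d):
        assert np.all(np.diff(solution_1d.strategies[0]) <= 1e-8)
        assert np.all(np.diff(solution_1d.values[0]) >= -1e-8)

    def test_feedback_slope_matches_stable_eigenvector(self):
        # derivative accuracy needs a finer node set and lighter ridge than
        # the value-level defaults
        from dyadgame.rbf import eval_rbf_deriv
        prob = benchmark_problem(1)
        cfg = SolverConfig(Q=61, kernel=KernelConfig(ridge=1e-7))
        sol = solve_hjb(prob, cfg)
        eq = equilibrium_closed_form(prob.partners[0], prob.r)
        slope = eval_rbf_deriv(sol.strategy_interp[0], eq.x, 1)
        assert slope == pytest.approx(-0.357, rel=0.15)

    def test_closed_loop_matches_shooting_oracle(self, solution_1d, config):
        prob = solution_1d.problem
        c0, path = shoot_initial_effort(3.0, prob.partners[0], prob.r,
                                        step=config.h)
        traj = simulate(solution_1d, 3.0, len(path.x) - 1, prob, config)
        scale = prob.x_hi - prob.x_lo
        assert np.max(np.abs(traj.x - path.x)) < 0.02 * scale

    def test_contraction_of_final_outer_passes(self, solution_1d):
        hist = solution_1d.report.value_change_history[-10:]
        # the tail of the outer iteration must not be growing
        assert max(hist[len(hist) // 2:]) <= max(hist[: len(hist) // 2])

    def test_strategies_within_control_bounds(self, solution_1d, config):
        assert np.all(solution_1d.strategies >= 0)
        assert np.all(solution_1d.strategies <= config.c_max)


class TestZeroUtility:
    def test_zero_utility_gives_preferred_effort_and_zero_value(self):
        p = PartnerSpec(rho=0.1, a=1.0,
                        utility=UtilityCurve(family="custom", func=lambda x: 0.0),
                        cost=EffortCost(cstar=0.2, w=1.0))
        prob = CoupleProblem(r=2.0, partners=(p,))
        sol = solve_hjb(prob, SolverConfig())
        assert np.max(np.abs(sol.strategies[0] - 0.2)) < 1e-6
        assert np.max(np.abs(sol.values[0])) < 1e-8

    def test_exact_solution_has_zero_bellman_residual(self):
        p = PartnerSpec(rho=0.1, a=1.0,
                        utility=UtilityCurve(family="custom", func=lambda x: 0.0),
                        cost=EffortCost(cstar=0.2, w=1.0))
        prob = CoupleProblem(r=2.0, partners=(p,))
        cfg = SolverConfig()
        sol = solve_hjb(prob, cfg)
        assert bellman_residual(sol, prob, cfg) < 1e-10


class TestBellmanResidual:
    def test_converged_run_within_tolerance_margin(self, solution_1d, config):
        res = bellman_residual(solution_1d, solution_1d.problem, config)
        assert res <= 10 * config.value_tol

    def test_value_perturbation_grows_residual_linearly(self, solution_1d, config):
        prob = solution_1d.problem
        delta = 1e-3
        # alternating-sign perturbation: a constant shift would be almost
        # annihilated by the discounted fixed-point structure
        signs = (-1.0) ** np.arange(solution_1d.nodes.Q)
        pert_values = solution_1d.values + delta * signs
        interp = tuple(
            fit_rbf(solution_1d.nodes, pert_values[i], config.kernel,
                    x_lo=prob.x_lo, x_hi=prob.x_hi)
            for i in range(prob.n_players))
        pert = FeedbackSolution(
            problem=prob, config=config, nodes=solution_1d.nodes,
            values=pert_values, strategies=solution_1d.strategies,
            value_interp=interp, strategy_interp=solution_1d.strategy_interp,
            report=solution_1d.report)
        res = bellman_residual(pert, prob, config)
        base = bellman_residual(solution_1d, prob, config)
        assert 0.01 * delta < res - base < 100 * delta


class TestSteadyState:
    def test_zero_efficiencies_decay_to_floor(self):
        p = PartnerSpec(rho=0.1, a=0.0)
        prob = CoupleProblem(r=2.0, partners=(p,))
        sol = solve_hjb(prob, SolverConfig())
        xbar, efforts = steady_state(sol, prob)
        assert xbar == 0.0
        assert efforts[0] == pytest.approx(0.2, abs=1e-6)


class TestConfigValidation:
    def test_time_step_bound(self):
        with pytest.raises(ValueError):
            solve_hjb(benchmark_problem(1), SolverConfig(h=0.6))  # 1 - r h < 0

    def test_bad_damping_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(damping=0.0)

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(value_tol=-1.0)
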