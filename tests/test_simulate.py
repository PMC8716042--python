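"""Closed-loop simulation, shocks, well-being accounting, recovery times."""

import numpy as np
import pytest

from dyadgame import (NodeSet, KernelConfig, ShockSequence, fit_rbf,
                      discounted_wellbeing, make_itch_shocks, recovery_time,
                      simulate, simulate_with_shocks, benchmark_problem)
from dyadgame.simulate import Trajectory
from dyadgame.solver import ConvergenceReport, FeedbackSolution, steady_state


class TestItchFixture:
    def test_default_schedule(self):
        shocks = make_itch_shocks()
        periods = shocks.nonzero_periods
        assert len(periods) == 12
        assert periods[0] == 85 and periods[-1] == 96
        vals = [shocks[k] for k in periods]
        assert vals[0] == pytest.approx(-0.15)
        assert vals[-1] == pytest.approx(-0.05)
        assert np.allclose(np.diff(vals), np.diff(vals)[0])  # linear ramp

    def test_shock_sum_is_arithmetic_series(self):
        shocks = make_itch_shocks()
        assert sum(shocks.shocks.values()) == pytest.approx(12 * -0.10)

    def test_single_shock(self):
        shocks = make_itch_shocks(count=1)
        assert shocks.nonzero_periods == [85]
        assert shocks[85] == pytest.approx(-0.15)

    def test_count_must_be_positive(self):
        with pytest.raises(ValueError):
            make_itch_shocks(count=0)

    def test_json_roundtrip(self):
        shocks = make_itch_shocks()
        clone = ShockSequence.from_json(shocks.to_json())
        assert clone.shocks == shocks.shocks
        assert clone.horizon == shocks.horizon


def _zero_strategy_solution(problem, config):
    """A synthetic solution whose strategies are identically zero, for the
    closed-form decay check."""
    nodes = config.make_nodes(problem)
    zero = fit_rbf(nodes, np.zeros(nodes.Q), config.kernel,
                   x_lo=problem.x_lo, x_hi=problem.x_hi)
    n = problem.n_players
    return FeedbackSolution(
        problem=problem, config=config, nodes=nodes,
        values=np.zeros((n, nodes.Q)), strategies=np.zeros((n, nodes.Q)),
        value_interp=(zero,) * n, strategy_interp=(zero,) * n,
        report=ConvergenceReport())


class TestSimulate:
    def test_stationary_start_stays_put(self, solution_1d, config):
        prob = solution_1d.problem
        xbar, _ = steady_state(solution_1d, prob)
        traj = simulate(solution_1d, xbar, 1000, prob, config)
        assert np.max(np.abs(traj.x - xbar)) < 1e-3

    def test_zero_strategies_decay_exactly(self, config):
        prob = benchmark_problem(1)
        sol = _zero_strategy_solution(prob, config)
        traj = simulate(sol, 3.0, 50, prob, config)
        expect = 3.0 * (1 - prob.r * config.h) ** np.arange(51)
        assert traj.x == pytest.approx(expect, rel=1e-12)

    def test_benchmark_run_monotone_toward_equilibrium(self, solution_1d, config):
        prob = solution_1d.problem
        traj = simulate(solution_1d, 3.0, 300, prob, config)
        assert np.all(np.diff(traj.x) < 0)
        assert np.all(np.diff(traj.efforts[0]) > 0)
        assert traj.x[-1] == pytest.approx(0.772, rel=0.05)

    def test_feeling_positivity(self, solution_1d, config):
        prob = solution_1d.problem
        traj = simulate(solution_1d, 0.05, 500, prob, config)
        assert np.all(traj.x >= 0)

    def test_frame_columns_consistent(self, solution_1d, config):
        traj = simulate(solution_1d, 3.0, 10, solution_1d.problem, config)
        frame = traj.to_frame()
        assert list(frame.columns) == ["k", "t", "x", "c1", "payoff1", "W1",
                                       "shocked"]
        assert len(frame) == 11

    def test_x0_outside_domain_rejected(self, solution_1d, config):
        with pytest.raises(ValueError):
            simulate(solution_1d, 9.0, 10, solution_1d.problem, config)


@pytest.fixture(scope="module")
def itch_run(solution_1d, config):
    prob = solution_1d.problem
    shocks = make_itch_shocks(horizon=450)
    pert = simulate_with_shocks(solution_1d, 3.0, shocks, prob, config)
    base = simulate(solution_1d, 3.0, 450, prob, config)
    return pert, base


class TestShockedSimulation:
    def test_zero_shocks_bitwise_identical_to_unperturbed(self, solution_1d, config):
        prob = solution_1d.problem
        base = simulate(solution_1d, 3.0, 300, prob, config)
        zero = simulate_with_shocks(solution_1d, 3.0, ShockSequence({}, 300),
                                    prob, config)
        assert np.array_equal(base.x, zero.x)
        assert np.array_equal(base.efforts, zero.efforts)
        assert np.array_equal(base.wellbeing, zero.wellbeing)

    def test_shock_depresses_feeling_below_unperturbed_minimum(self, itch_run):
        pert, base = itch_run
        assert pert.x.min() < base.x.min()

    def test_path_rejoins_baseline_after_recovery(self, itch_run):
        pert, base = itch_run
        gap = np.abs(pert.x[-1] - base.x[-1])
        assert gap < 0.01 * base.x[-1]

    def test_u_shape_unique_minimum_then_nondecreasing(self, itch_run):
        pert, base = itch_run
        onset = int(np.argmax(pert.shocked))
        after = pert.x[onset:]
        k_min = int(np.argmin(after))
        assert np.sum(after == after.min()) == 1
        # non-decreasing from the nadir until re-joining the baseline
        rejoin = onset + k_min + int(np.argmax(
            np.abs(pert.x[onset + k_min:] - base.x[onset + k_min:])
            < 0.01 * base.x[onset + k_min:]))
        assert np.all(np.diff(pert.x[onset + k_min:rejoin + 1]) >= 0)

    def test_recovery_needs_effort_above_unperturbed(self, itch_run):
        pert, base = itch_run
        last_shock = int(np.where(pert.shocked)[0][-1])
        window = slice(last_shock + 1, last_shock + 100)
        assert np.all(pert.efforts[0][window] > base.efforts[0][window])


class TestDiscountedWellbeing:
    def test_zero_payoffs_give_zero(self, config):
        prob = benchmark_problem(1)
        traj = Trajectory(h=config.h, x=np.zeros(10),
                          efforts=np.full((1, 10), 0.2),
                          payoffs=np.zeros((1, 10)),
                          wellbeing=np.zeros((1, 10)),
                          shocked=np.zeros(10, bool))
        assert discounted_wellbeing(traj, prob.partners[0], config) == 0.0

    def test_constant_payoff_matches_geometric_sum(self, config):
        prob = benchmark_problem(1)
        p = 2.0
        n = 500
        traj = Trajectory(h=config.h, x=np.zeros(n),
                          efforts=np.zeros((1, n)),
                          payoffs=np.full((1, n), p),
                          wellbeing=np.zeros((1, n)),
                          shocked=np.zeros(n, bool))
        rho = prob.partners[0].rho
        q = np.exp(-rho * config.h)
        expect = config.h * p * (1 - q**n) / (1 - q)
        got = discounted_wellbeing(traj, prob.partners[0], config)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_agrees_with_value_function(self, solution_1d, config):
        prob = solution_1d.problem
        traj = simulate(solution_1d, 3.0, 12000, prob, config)
        W = discounted_wellbeing(traj, prob.partners[0], config)
        assert W == pytest.approx(solution_1d.value(0, 3.0), rel=0.02)


class TestRecoveryTime:
    def test_never_below_threshold_is_zero(self, solution_1d, config):
        prob = solution_1d.problem
        xbar, _ = steady_state(solution_1d, prob)
        traj = simulate(solution_1d, xbar, 100, prob, config)
        assert recovery_time(traj, xbar).periods == 0

    def test_linear_decay_toy_matches_logarithmic_estimate(self, config):
        # pure exponential approach to a baseline after a one-period shock:
        # periods ~ ln(|s| / (0.05 b)) / (lam h)
        lam, b, s, h = 2.0, 1.0, -0.3, config.h
        n = 2000
        x = np.empty(n)
        x[0] = b + s
        for k in range(n - 1):
            x[k + 1] = x[k] + h * lam * (b - x[k])
        shocked = np.zeros(n, bool)
        shocked[0] = True
        traj = Trajectory(h=h, x=x, efforts=np.zeros((1, n)),
                          payoffs=np.zeros((1, n)),
                          wellbeing=np.zeros((1, n)), shocked=shocked)
        got = recovery_time(traj, b).periods
        expect = np.log(abs(s) / (0.05 * b)) / (lam * h)
        assert got == pytest.approx(expect, rel=0.1)

    def test_nonrecovery_flagged(self, config):
        x = np.full(50, 0.1)
        shocked = np.zeros(50, bool)
        shocked[1] = True
        traj = Trajectory(h=config.h, x=x, efforts=np.zeros((1, 50)),
                          payoffs=np.zeros((1, 50)),
                          wellbeing=np.zeros((1, 50)), shocked=shocked)
        res = recovery_time(traj, 1.0)
        assert not res.recovered
        assert res.periods == 48

    def test_baseline_must_be_positive(self, solution_1d, config):
        traj = simulate(solution_1d, 3.0, 10, solution_1d.problem, config)
        with pytest.raises(ValueError):
            recovery_time(traj, 0.0)
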