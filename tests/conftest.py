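"""Shared fixtures: solved benchmark problems are expensive, so they are
computed once per session and shared across test modules."""

import pytest

from dyadgame import SolverConfig, solve_hjb, benchmark_problem


@pytest.fixture(scope="session")
def config():
    return SolverConfig()


@pytest.fixture(scope="session")
def solution_1d(config):
    """Feedback solution of the benchmark 1D couple-as-a-unit problem."""
    return solve_hjb(benchmark_problem(1), config)


@pytest.fixture(scope="session")
def solve_2d(config):
    """Memoized 2D game solves keyed by partner 2's efficiency a2."""
    cache = {}

    def get(a2: float):
        if a2 not in cache:
            cache[a2] = solve_hjb(benchmark_problem(2, 1.0, a2), config)
        return cache[a2]

    return get
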