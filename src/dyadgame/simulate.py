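"""Closed-loop trajectory simulation and feedback stabilization.

Once feedback strategies are solved, the relationship's evolution from any
initial feeling follows the Euler recursion

    c_{i,k} = S_i(x_k),    x_{k+1} = x_k + h f(x_k, c_{1,k}, c_{2,k}),

optionally perturbed by a sparse schedule of additive feeling shocks
(``x_{k+1} <- x_{k+1} + sigma_{k+1}``), against which the partners react
optimally because their strategies condition on the observed state.  The
module also accounts discounted well-being along a path and measures the
time to recover a fraction of a baseline feeling after a shock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import CoupleProblem, PartnerSpec
from .solver import FeedbackSolution, SolverConfig

__all__ = [
    "ShockSequence",
    "Trajectory",
    "RecoveryResult",
    "simulate",
    "simulate_with_shocks",
    "discounted_wellbeing",
    "recovery_time",
    "make_itch_shocks",
]


@dataclass(frozen=True)
class ShockSequence:
    """Sparse schedule of additive feeling shocks by period index (>= 1).

    Periods not listed carry a zero shock.
    """

    shocks: Mapping[int, float] = field(default_factory=dict)
    horizon: int = 300

    def __post_init__(self) -> None:
        for k in self.shocks:
            if not (isinstance(k, (int, np.integer)) and k >= 1):
                raise ValueError("shock period indices must be integers >= 1")

    def __getitem__(self, k: int) -> float:
        return float(self.shocks.get(int(k), 0.0))

    @property
    def nonzero_periods(self) -> list[int]:
        return sorted(k for k, v in self.shocks.items() if v != 0.0)

    def to_json(self) -> str:
        return json.dumps({"horizon": self.horizon,
                           "shocks": {str(k): v for k, v in self.shocks.items()}})

    @classmethod
    def from_json(cls, text: str) -> "ShockSequence":
        d = json.loads(text)
        return cls(shocks={int(k): float(v) for k, v in d["shocks"].items()},
                   horizon=int(d["horizon"]))


def make_itch_shocks(start: int = 85, count: int = 12,
                     first: float = -0.15, last: float = -0.05,
                     horizon: int = 300) -> ShockSequence:
    """The bundled stress fixture: a run of consecutive negative feeling
    shocks around the seventh "year" of the relationship, linearly ramped
    from ``first`` to ``last`` over ``count`` periods starting at ``start``.
    """
    if count < 1:
        raise ValueError("count must be at least 1")
    vals = np.linspace(first, last, count) if count > 1 else np.array([first])
    return ShockSequence(shocks={start + j: float(vals[j]) for j in range(count)},
                         horizon=horizon)


@dataclass
class Trajectory:
    """Discrete time series of a closed-loop run.

    All arrays have length ``n + 1`` (periods ``k = 0 .. n``).  ``efforts``
    and ``payoffs`` have shape ``(n_players, n + 1)``; ``wellbeing`` holds
    the running discounted partial sums of ``h exp(-rho t_k) (U - D)``.
    ``breakdown`` flags a dip of the feeling below the viability threshold
    ``x_min`` (computation is never halted); ``clamped`` flags clipping of
    the state to the domain.
    """

    h: float
    x: np.ndarray
    efforts: np.ndarray
    payoffs: np.ndarray
    wellbeing: np.ndarray
    shocked: np.ndarray
    breakdown: bool = False
    first_breakdown: int | None = None
    clamped: bool = False

    @property
    def k(self) -> np.ndarray:
        return np.arange(self.x.size)

    @property
    def t(self) -> np.ndarray:
        return self.h * self.k

    def to_frame(self) -> pd.DataFrame:
        n_players = self.efforts.shape[0]
        data = {"k": self.k, "t": self.t, "x": self.x}
        for i in range(n_players):
            data[f"c{i+1}"] = self.efforts[i]
        for i in range(n_players):
            data[f"payoff{i+1}"] = self.payoffs[i]
        for i in range(n_players):
            data[f"W{i+1}"] = self.wellbeing[i]
        data["shocked"] = self.shocked
        return pd.DataFrame(data)


def _run(solution: FeedbackSolution, x0: float, n: int,
         problem: CoupleProblem, config: SolverConfig,
         shocks: ShockSequence | None) -> Trajectory:
    if n < 1:
        raise ValueError("need at least one period")
    if not (problem.x_lo <= x0 <= problem.x_hi):
        raise ValueError("x0 outside the state domain")
    h = config.h
    n_players = problem.n_players
    a = problem.efficiencies()
    x = np.empty(n + 1)
    efforts = np.empty((n_players, n + 1))
    payoffs = np.empty((n_players, n + 1))
    shocked = np.zeros(n + 1, dtype=bool)
    clamped = False
    x[0] = x0
    for k in range(n + 1):
        xk = x[k]
        ck = solution.strategies_at(xk)
        efforts[:, k] = ck
        for i, p in enumerate(problem.partners):
            payoffs[i, k] = p.utility(xk) - p.cost(ck[i])
        if k == n:
            break
        x_next = xk + h * (-problem.r * xk + float(a @ ck))
        if shocks is not None:
            sigma = shocks[k + 1]
            if sigma != 0.0:
                x_next += sigma
                shocked[k + 1] = True
        if x_next < problem.x_lo or x_next > problem.x_hi:
            x_next = min(max(x_next, problem.x_lo), problem.x_hi)
            clamped = True
        x[k + 1] = x_next
    wellbeing = np.empty_like(payoffs)
    t = h * np.arange(n + 1)
    for i, p in enumerate(problem.partners):
        wellbeing[i] = np.cumsum(h * np.exp(-p.rho * t) * payoffs[i])
    below = x < problem.x_min
    first = int(np.argmax(below)) if below.any() else None
    return Trajectory(h=h, x=x, efforts=efforts, payoffs=payoffs,
                      wellbeing=wellbeing, shocked=shocked,
                      breakdown=below.any(), first_breakdown=first,
                      clamped=clamped)


def simulate(solution: FeedbackSolution, x0: float, n: int,
             problem: CoupleProblem, config: SolverConfig) -> Trajectory:
    """Unperturbed closed-loop run of ``n`` periods from feeling ``x0``."""
    return _run(solution, x0, n, problem, config, shocks=None)


def simulate_with_shocks(solution: FeedbackSolution, x0: float,
                         shocks: ShockSequence, problem: CoupleProblem,
                         config: SolverConfig,
                         n: int | None = None) -> Trajectory:
    """Shock-perturbed run: the schedule's perturbation is added after each
    Euler update and the partners respond to the observed (perturbed) state
    in the following period.  With an all-zero schedule this reproduces
    :func:`simulate` bitwise.
    """
    n = shocks.horizon if n is None else n
    return _run(solution, x0, n, problem, config, shocks=shocks)


def discounted_wellbeing(traj: Trajectory, partner: PartnerSpec,
                         config: SolverConfig,
                         payoff_row: int = 0) -> float:
    """Total discounted well-being ``h sum_k exp(-rho t_k) (U(x_k) - D(c_k))``
    accumulated over the recorded horizon."""
    if traj.x.size == 0:
        raise ValueError("empty trajectory")
    t = traj.t
    payoff = traj.payoffs[payoff_row]
    return float(np.sum(config.h * np.exp(-partner.rho * t) * payoff))


@dataclass(frozen=True)
class RecoveryResult:
    periods: int
    recovered: bool


def recovery_time(perturbed: Trajectory, baseline: float,
                  fraction: float = 0.95) -> RecoveryResult:
    """Periods from the first shock until the feeling first regains
    ``fraction * baseline``.

    Returns 0 if the feeling never drops below the threshold.  If it never
    recovers within the recorded horizon, the remaining horizon length is
    reported with ``recovered=False``.
    """
    if not baseline > 0:
        raise ValueError("baseline must be positive")
    threshold = fraction * baseline
    if not perturbed.shocked.any():
        k0 = 0
    else:
        k0 = int(np.argmax(perturbed.shocked))
    tail = perturbed.x[k0:]
    if np.all(tail >= threshold):
        return RecoveryResult(0, True)
    first_below = int(np.argmax(tail < threshold))
    after = tail[first_below:]
    if np.all(after < threshold):
        return RecoveryResult(tail.size - 1, False)
    rec = first_below + int(np.argmax(after >= threshold))
    return RecoveryResult(rec, True)
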