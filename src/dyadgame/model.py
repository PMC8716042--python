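"""Model objects for the couple's effort control problem.

The state of the relationship is a scalar *feeling* ``x(t)`` that decays at
rate ``r`` unless counteracted by the partners' efforts ``c_i(t)``, which
enter the dynamics additively with per-partner efficiencies ``a_i``:

    dx/dt = -r x + a1 c1 + a2 c2.

Each partner accrues discounted well-being ``∫ exp(-rho_i t) (U_i(x) -
D_i(c_i)) dt`` where ``U_i`` is an increasing concave utility of feeling and
``D_i`` a convex disutility of effort with interior minimum at the preferred
effort level ``c_i*``.  A single-partner problem treats the couple as a unit
(one effort, one happiness integral); the two-partner problem is a
nonzero-sum differential game.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "UtilityCurve",
    "EffortCost",
    "PartnerSpec",
    "CoupleProblem",
    "ValidationCheck",
    "ValidationReport",
    "drift",
    "instantaneous_payoff",
    "validate_problem",
    "benchmark_problem",
    "load_problem",
]


# ---------------------------------------------------------------------------
# utility and cost curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtilityCurve:
    """Instantaneous utility of feeling, ``U(x)``.

    The default family is logarithmic, ``U(x) = alpha * ln(x + 1)``, which is
    increasing, strictly concave and satiating (``U' -> 0`` as ``x -> inf``).
    A user-supplied smooth function may be passed instead via ``func`` (with
    optional analytic derivatives; otherwise central differences are used).

    Parameters
    ----------
    alpha:
        Scale coefficient of the log family, in well-being units. Default 5.
    family:
        ``"log"`` or ``"custom"``.
    func, dfunc, d2func:
        Custom value / first / second derivative callables (``family ==
        "custom"`` only).
    """

    alpha: float = 5.0
    family: str = "log"
    func: Callable[[float], float] | None = None
    dfunc: Callable[[float], float] | None = None
    d2func: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("log", "custom"):
            raise ValueError(f"unknown utility family {self.family!r}")
        if self.family == "custom" and self.func is None:
            raise ValueError("custom utility requires func")

    def __call__(self, x):
        if self.family == "log":
            return self.alpha * np.log(np.asarray(x, dtype=float) + 1.0)
        return np.vectorize(self.func, otypes=[float])(x)[()]

    def prime(self, x):
        if self.family == "log":
            return self.alpha / (np.asarray(x, dtype=float) + 1.0)
        if self.dfunc is not None:
            return np.vectorize(self.dfunc, otypes=[float])(x)[()]
        return _central_diff(self, x, order=1)

    def second(self, x):
        if self.family == "log":
            return -self.alpha / (np.asarray(x, dtype=float) + 1.0) ** 2
        if self.d2func is not None:
            return np.vectorize(self.d2func, otypes=[float])(x)[()]
        return _central_diff(self, x, order=2)


@dataclass(frozen=True)
class EffortCost:
    """Instantaneous disutility of effort, ``D(c)``.

    Default family is quadratic, ``D(c) = w/2 (c - c*)^2``: zero cost and
    zero marginal cost at the preferred effort ``c*``, increasingly painful
    beyond it.  Depends on own effort only.

    Parameters
    ----------
    cstar:
        Preferred effort level ``c* >= 0`` (effort units). Default 0.2.
    w:
        Curvature weight ``w > 0`` (default 1).
    """

    cstar: float = 0.2
    w: float = 1.0
    family: str = "quadratic"
    func: Callable[[float], float] | None = None
    dfunc: Callable[[float], float] | None = None
    d2func: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("quadratic", "custom"):
            raise ValueError(f"unknown cost family {self.family!r}")
        if self.family == "custom" and self.func is None:
            raise ValueError("custom cost requires func")

    def __call__(self, c):
        if self.family == "quadratic":
            return 0.5 * self.w * (np.asarray(c, dtype=float) - self.cstar) ** 2
        return np.vectorize(self.func, otypes=[float])(c)[()]

    def prime(self, c):
        if self.family == "quadratic":
            return self.w * (np.asarray(c, dtype=float) - self.cstar)
        if self.dfunc is not None:
            return np.vectorize(self.dfunc, otypes=[float])(c)[()]
        return _central_diff(self, c, order=1)

    def second(self, c):
        if self.family == "quadratic":
            return self.w * np.ones_like(np.asarray(c, dtype=float))[()]
        if self.d2func is not None:
            return np.vectorize(self.d2func, otypes=[float])(c)[()]
        return _central_diff(self, c, order=2)


def _central_diff(f, x, order: int, eps: float = 1e-5):
    x = np.asarray(x, dtype=float)
    if order == 1:
        return (f(x + eps) - f(x - eps)) / (2 * eps)
    return (f(x + eps) - 2 * f(x) + f(x - eps)) / eps**2


# ---------------------------------------------------------------------------
# partner and couple specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartnerSpec:
    """One partner: time preference, effort efficiency, utility and cost.

    ``rho`` is the rate of time preference (per unit time, > 0) and ``a`` the
    efficiency of a unit of effort (feeling per effort per unit time, >= 0).
    """

    rho: float = 0.1
    a: float = 1.0
    utility: UtilityCurve = field(default_factory=UtilityCurve)
    cost: EffortCost = field(default_factory=EffortCost)

    def __post_init__(self) -> None:
        # rho = 0 is constructible so that validate_problem can report the
        # failed discounting check; the solver rejects it separately
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not (np.isfinite(self.a) and self.a >= 0):
            raise ValueError("a must be finite and non-negative")


@dataclass(frozen=True)
class CoupleProblem:
    """Full game definition.

    One partner gives the 1D couple-as-a-unit control problem; two partners
    give the dyadic differential game.  ``x_min`` is the viability threshold:
    a trajectory dipping below it is flagged as a breakdown but simulation is
    never halted.
    """

    r: float = 2.0
    partners: tuple[PartnerSpec, ...] = ()
    x_lo: float = 0.0
    x_hi: float = 5.0
    x_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("decay rate r must be positive")
        if len(self.partners) not in (1, 2):
            raise ValueError("problem must have 1 or 2 partners")
        if not self.x_lo < self.x_hi:
            raise ValueError("domain must satisfy x_lo < x_hi")
        if not (self.x_lo <= self.x_min <= self.x_hi):
            raise ValueError("x_min must lie within the state domain")

    @property
    def n_players(self) -> int:
        return len(self.partners)

    def efficiencies(self) -> np.ndarray:
        return np.array([p.a for p in self.partners])


def drift(x: float, c1: float, c2: float | None, problem: CoupleProblem):
    """Feeling dynamics ``f(x, c1, c2) = -r x + a1 c1 + a2 c2``.

    For a single-partner problem pass ``c2=None`` (or 0).
    """
    efforts = [c1] if problem.n_players == 1 else [c1, c2]
    total = 0.0
    for p, c in zip(problem.partners, efforts):
        if c is None:
            raise ValueError("missing effort for a partner")
        if np.any(np.asarray(c) < 0):
            raise ValueError("efforts must be non-negative")
        total = total + p.a * np.asarray(c, dtype=float)
    return -problem.r * np.asarray(x, dtype=float) + total


def instantaneous_payoff(x, c, partner: PartnerSpec):
    """Well-being rate ``U(x) - D(c)`` of one partner."""
    if np.any(np.asarray(x) < 0) or np.any(np.asarray(c) < 0):
        raise ValueError("feeling and effort must be non-negative")
    return partner.utility(x) - partner.cost(c)


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[ValidationCheck, ...]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]


def validate_problem(problem: CoupleProblem, n_grid: int = 64) -> ValidationReport:
    """Check the structural assumptions of the model on a sample grid.

    Failures are reported, never raised: utility increasing and concave,
    marginal utility satiating, cost convex with interior minimum at ``c*``,
    positive discounting and decay, non-negative efficiencies, well-ordered
    domain.
    """
    checks: list[ValidationCheck] = []
    checks.append(ValidationCheck("decay_positive", problem.r > 0, f"r={problem.r}"))
    checks.append(
        ValidationCheck(
            "domain_ordered", problem.x_lo < problem.x_hi,
            f"[{problem.x_lo}, {problem.x_hi}]",
        )
    )
    xs = np.linspace(max(problem.x_lo, 0.0), problem.x_hi, n_grid)
    for i, p in enumerate(problem.partners, start=1):
        tag = f"partner{i}"
        u = p.utility(xs)
        du = np.diff(u)
        checks.append(ValidationCheck(f"{tag}_utility_increasing", bool(np.all(du > 0))))
        checks.append(ValidationCheck(f"{tag}_utility_concave", bool(np.all(np.diff(du) < 0))))
        checks.append(
            ValidationCheck(
                f"{tag}_utility_satiating",
                bool(p.utility.prime(1e3) < p.utility.prime(10.0)),
            )
        )
        cs = np.linspace(0.0, max(2.0 * p.cost.cstar + 1.0, 1.0), n_grid)
        d = p.cost(cs)
        checks.append(ValidationCheck(f"{tag}_cost_convex", bool(np.all(np.diff(d, 2) > 0))))
        checks.append(
            ValidationCheck(
                f"{tag}_cost_minimum_at_cstar",
                bool(abs(p.cost(p.cost.cstar)) < 1e-12 and abs(p.cost.prime(p.cost.cstar)) < 1e-12)
                if p.cost.family == "quadratic"
                else bool(abs(p.cost.prime(p.cost.cstar)) < 1e-6),
            )
        )
        checks.append(ValidationCheck(f"{tag}_discounting", p.rho > 0, f"rho={p.rho}"))
        checks.append(ValidationCheck(f"{tag}_efficiency", np.isfinite(p.a) and p.a >= 0, f"a={p.a}"))
    return ValidationReport(tuple(checks))


# ---------------------------------------------------------------------------
# bundled defaults and configuration files
# ---------------------------------------------------------------------------

def benchmark_problem(players: int = 1, a1: float = 1.0, a2: float = 1.0) -> CoupleProblem:
    """Benchmark configuration used throughout: r = 2, rho = 0.1,
    U(x) = 5 ln(x+1), D(c) = (c - 0.2)^2 / 2, domain [0, 5].
    """
    mk = lambda a: PartnerSpec(rho=0.1, a=a, utility=UtilityCurve(alpha=5.0),
                               cost=EffortCost(cstar=0.2, w=1.0))
    if players == 1:
        return CoupleProblem(r=2.0, partners=(mk(a1),))
    return CoupleProblem(r=2.0, partners=(mk(a1), mk(a2)))


def problem_from_dict(cfg: dict) -> CoupleProblem:
    """Build a :class:`CoupleProblem` from a flat key-value mapping.

    Recognized keys: ``r, a1, a2, rho1, rho2, cstar1, cstar2, alpha1,
    alpha2, w1, w2, x_lo, x_hi, x_min, players``.  ``players`` defaults to 2
    when any partner-2 key is present, else 1.
    """
    keys2 = {"a2", "rho2", "cstar2", "alpha2", "w2"}
    players = int(cfg.get("players", 2 if keys2 & set(cfg) else 1))
    partners = []
    for i in range(1, players + 1):
        partners.append(
            PartnerSpec(
                rho=float(cfg.get(f"rho{i}", 0.1)),
                a=float(cfg.get(f"a{i}", 1.0)),
                utility=UtilityCurve(alpha=float(cfg.get(f"alpha{i}", 5.0))),
                cost=EffortCost(cstar=float(cfg.get(f"cstar{i}", 0.2)),
                                w=float(cfg.get(f"w{i}", 1.0))),
            )
        )
    return CoupleProblem(
        r=float(cfg.get("r", 2.0)),
        partners=tuple(partners),
        x_lo=float(cfg.get("x_lo", 0.0)),
        x_hi=float(cfg.get("x_hi", 5.0)),
        x_min=float(cfg.get("x_min", 0.0)),
    )


def load_problem(path: str | Path) -> CoupleProblem:
    """Read a problem definition from a JSON or TOML config file."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        cfg = tomllib.loads(path.read_text())
    else:
        cfg = json.loads(path.read_text())
    return problem_from_dict(cfg)
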