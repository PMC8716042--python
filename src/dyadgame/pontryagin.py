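"""Saddle-path analysis of the one-dimensional couple's problem.

For a single-partner (couple-as-a-unit) problem, the maximum principle turns
the optimal control problem into a planar effort-feeling system

    dx/dt = -r x + a c
    dc/dt = (1 / D''(c)) * [ (r + rho) D'(c) - a U'(x) ]

whose unique positive equilibrium is a saddle; the optimal trajectory is the
stable manifold.  This module provides the vector field, a classical RK4
integrator, the closed-form equilibrium, saddle classification, and a
shooting routine that finds the initial effort placing the trajectory on the
stable manifold.  It serves as an independent oracle for the HJB feedback
solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import PartnerSpec

__all__ = [
    "PhasePoint",
    "Equilibrium1D",
    "PhasePath",
    "field",
    "rk4_integrate",
    "equilibrium_closed_form",
    "classify_saddle",
    "shoot_initial_effort",
]


@dataclass(frozen=True)
class PhasePoint:
    """A point of the effort-feeling phase plane."""

    x: float
    c: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.c)):
            raise ValueError("phase point must be finite")


@dataclass(frozen=True)
class Equilibrium1D:
    """Stationary (feeling, effort) pair with its local classification."""

    x: float
    c: float
    eigenvalues: tuple[float, float]
    classification: str  # "saddle" | "other"


@dataclass(frozen=True)
class PhasePath:
    """RK4 output: times and the (x, c) path; ``truncated`` marks blow-up."""

    t: np.ndarray
    x: np.ndarray
    c: np.ndarray
    truncated: bool = False


def field(p: PhasePoint, partner: PartnerSpec, r: float,
          use_u_prime: bool = True) -> tuple[float, float]:
    """Phase velocity (dx/dt, dc/dt) of the effort-feeling system.

    ``use_u_prime=False`` substitutes U(x) for U'(x) in the costate term
    (an alternative, non-standard form of the system); the derivative form
    is the default as it is the one consistent with the maximum principle
    and with the benchmark equilibrium.
    """
    d2 = float(partner.cost.second(p.c))
    if d2 == 0.0:
        raise ZeroDivisionError("D''(c) = 0: effort dynamics undefined")
    ugrad = float(partner.utility.prime(p.x)) if use_u_prime else float(partner.utility(p.x))
    dx = -r * p.x + partner.a * p.c
    dc = ((r + partner.rho) * float(partner.cost.prime(p.c)) - partner.a * ugrad) / d2
    return (dx, dc)


def rk4_integrate(p0: PhasePoint, partner: PartnerSpec, r: float,
                  step: float, n_steps: int,
                  use_u_prime: bool = True) -> PhasePath:
    """Classical 4th-order Runge-Kutta path of the phase system.

    A non-finite (or wildly diverging) state truncates the path and sets the
    ``truncated`` flag.
    """
    if not step > 0:
        raise ValueError("step must be positive")
    # plain-float inner loop: the system is tiny and this is much faster
    # than array arithmetic
    a, rho = partner.a, partner.rho
    xs = [p0.x]
    cs = [p0.c]
    x, c = p0.x, p0.c
    truncated = False

    def f(x, c):
        d2 = float(partner.cost.second(c))
        ug = float(partner.utility.prime(x)) if use_u_prime else float(partner.utility(x))
        return (-r * x + a * c,
                ((r + rho) * float(partner.cost.prime(c)) - a * ug) / d2)

    for _ in range(n_steps):
        try:
            k1 = f(x, c)
            k2 = f(x + 0.5 * step * k1[0], c + 0.5 * step * k1[1])
            k3 = f(x + 0.5 * step * k2[0], c + 0.5 * step * k2[1])
            k4 = f(x + step * k3[0], c + step * k3[1])
        except (ValueError, OverflowError, ZeroDivisionError):
            truncated = True
            break
        x = x + step / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        c = c + step / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if not (math.isfinite(x) and math.isfinite(c)) or abs(x) > 1e8 or abs(c) > 1e8:
            truncated = True
            break
        xs.append(x)
        cs.append(c)
    t = step * np.arange(len(xs))
    return PhasePath(t=t, x=np.array(xs), c=np.array(cs), truncated=truncated)


def equilibrium_closed_form(partner: PartnerSpec, r: float) -> Equilibrium1D:
    """Stationary point of the phase system.

    Solves ``-r x + a c = 0`` and ``(r + rho) D'(c) = a U'(x)``.  For the
    log/quadratic family this reduces to one quadratic in ``c``; the
    positive root is returned.  Other families use a safeguarded Newton
    iteration on the same two equations.
    """
    a, rho = partner.a, partner.rho
    if a == 0.0:
        # decoupled: x decays to 0, effort rests at its preferred level
        eq = Equilibrium1D(0.0, float(partner.cost.cstar), (0.0, 0.0), "other")
        return classify_saddle(eq, partner, r)
    if partner.utility.family == "log" and partner.cost.family == "quadratic":
        alpha = partner.utility.alpha
        cstar, w = partner.cost.cstar, partner.cost.w
        # (r+rho) w (c - c*) (a c / r + 1) = a alpha
        A = a / r
        poly = [A, 1.0 - A * cstar, -cstar - a * alpha / ((r + rho) * w)]
        roots = np.roots(poly)
        pos = [float(z.real) for z in roots if abs(z.imag) < 1e-12 and z.real > 0]
        if not pos:
            raise ValueError("no positive stationary effort for these inputs")
        c = max(pos)
        x = a * c / r
    else:
        from scipy.optimize import fsolve

        def eqs(z):
            x_, c_ = z
            return [
                -r * x_ + a * c_,
                (r + rho) * float(partner.cost.prime(c_)) - a * float(partner.utility.prime(x_)),
            ]

        x, c = fsolve(eqs, [1.0, 1.0], full_output=False)
        if c <= 0:
            raise ValueError("no positive stationary effort for these inputs")
    eq = Equilibrium1D(float(x), float(c), (0.0, 0.0), "other")
    res = field(PhasePoint(eq.x, eq.c), partner, r)
    if max(abs(res[0]), abs(res[1])) > 1e-8:
        raise ValueError(f"stationarity residual too large: {res}")
    return classify_saddle(eq, partner, r)


def classify_saddle(eq: Equilibrium1D, partner: PartnerSpec, r: float) -> Equilibrium1D:
    """Attach Jacobian eigenvalues and the saddle/other tag to ``eq``.

    The Jacobian at the stationary point is
    ``[[-r, a], [-a U''(x)/D''(c), r + rho]]``; a negative determinant marks
    a saddle, which for increasing-concave U and convex D is always the case.
    """
    d2 = float(partner.cost.second(eq.c))
    J = np.array([
        [-r, partner.a],
        [-partner.a * float(partner.utility.second(eq.x)) / d2, r + partner.rho],
    ])
    ev = np.sort(np.linalg.eigvals(J).real)
    tag = "saddle" if float(np.linalg.det(J)) < 0 else "other"
    return Equilibrium1D(eq.x, eq.c, (float(ev[0]), float(ev[1])), tag)


def stable_eigenvector_slope(eq: Equilibrium1D, partner: PartnerSpec, r: float) -> float:
    """Slope dc/dx of the stable manifold at the equilibrium."""
    lam = min(eq.eigenvalues)
    # from the first Jacobian row: (-r - lam) vx + a vc = 0
    return (lam + r) / partner.a


def shoot_initial_effort(
    x0: float,
    partner: PartnerSpec,
    r: float,
    step: float = 1e-3,
    horizon: float = 10.0,
    c_max: float = 5.0,
    tol: float = 1e-6,
    tube_radius: float | None = None,
) -> tuple[float, PhasePath]:
    """Find the initial effort placing ``(x0, c0)`` on the stable manifold.

    Bisection on ``c0 in [0, c_max]``: paths with too much initial effort
    escape upward (effort blows up), too little escape downward.  The
    returned path is the RK4 trajectory from the bisected ``c0``; it stays
    within a tube around the equilibrium and converges toward it.
    """
    if not x0 > 0:
        raise ValueError("x0 must be positive")
    eq = equilibrium_closed_form(partner, r)
    scale = max(abs(x0), abs(eq.x), 1.0)
    tube = tube_radius if tube_radius is not None else 5.0 * scale
    n_steps = int(round(horizon / step))
    # classification thresholds: paths above the manifold blow up along the
    # unstable direction (x and c both large positive); paths below crash
    # (effort turns negative, feeling collapses).  The tests must trigger
    # while the state is still in the physically meaningful region -- for
    # the log family the costate term is singular at x = -1 and flips sign
    # beyond it, so the final point of a crashed path is uninformative.
    c_floor = min(0.0, eq.c) - 0.5 * scale
    x_floor = max(-0.9, eq.x - tube) if partner.utility.family == "log" else eq.x - tube

    def escape_side(c0: float) -> int:
        """+1 if the path escapes upward, -1 downward, 0 if it stays near
        the equilibrium for the whole horizon."""
        path = rk4_integrate(PhasePoint(x0, c0), partner, r, step, n_steps)
        up = (path.c > eq.c + tube) | (path.x > max(x0, eq.x) + tube)
        down = (path.c < c_floor) | (path.x < x_floor)
        k_up = int(np.argmax(up)) if up.any() else n_steps + 1
        k_down = int(np.argmax(down)) if down.any() else n_steps + 1
        if k_up <= n_steps or k_down <= n_steps:
            return 1 if k_up < k_down else -1
        if path.truncated:
            return 1 if path.c[-1] > eq.c else -1
        return 0

    lo, hi = 0.0, c_max
    side_lo, side_hi = escape_side(lo), escape_side(hi)
    if side_lo == 0:
        return lo, rk4_integrate(PhasePoint(x0, lo), partner, r, step, n_steps)
    if side_lo > 0 or side_hi < 0:
        raise ValueError(
            f"shooting bracket [0, {c_max}] does not straddle the stable "
            f"manifold (sides {side_lo}, {side_hi}); widen c_max"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        s = escape_side(mid)
        if s == 0:
            lo = hi = mid
            break
        if s > 0:
            hi = mid
        else:
            lo = mid
    c0 = 0.5 * (lo + hi)
    path = rk4_integrate(PhasePoint(x0, c0), partner, r, step, n_steps)
    # the bisected c0 is accurate to `tol` only, so the tail of the raw path
    # eventually leaves the saddle along the unstable direction; cut the
    # returned path at its closest approach to the equilibrium
    dist = np.maximum(np.abs(path.x - eq.x), np.abs(path.c - eq.c))
    k = int(np.argmin(dist)) + 1
    return c0, PhasePath(t=path.t[:k], x=path.x[:k], c=path.c[:k],
                         truncated=path.truncated)
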