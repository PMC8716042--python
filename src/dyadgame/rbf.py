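"""Mesh-free radial-basis-function interpolation on scattered feeling nodes.

Value and strategy functions live on a set of ``Q`` scattered nodes in the
feeling domain; the semi-Lagrangian update needs their values off-node (at
the Euler image of the state), which is what these interpolants provide.

The interpolant is the symmetric collocation expansion

    s(x) = sum_j lam_j phi(|x - y_j|) + g0 + g1 x,

with a Gaussian kernel ``phi(r) = exp(-eps r^2)`` by default (multiquadric
``sqrt(1 + (eps r)^2)`` selectable).  The optional linear polynomial tail
makes constants and affine functions reproduce exactly, which stabilizes the
value iteration; a small ridge term guards the collocation solve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = ["NodeSet", "KernelConfig", "RBFInterpolant", "fit_rbf", "eval_rbf"]


@dataclass(frozen=True)
class NodeSet:
    """``Q >= 3`` distinct node locations inside ``[x_lo, x_hi]``."""

    points: np.ndarray
    scheme: str = "uniform"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 1:
            raise ValueError("nodes must be a non-empty 1-d array")
        if np.unique(pts).size != pts.size:
            raise ValueError("nodes must be distinct")

    @property
    def Q(self) -> int:
        return self.points.size

    @property
    def spacing(self) -> float:
        return float(np.mean(np.diff(np.sort(self.points))))

    @classmethod
    def uniform(cls, x_lo: float, x_hi: float, Q: int = 41) -> "NodeSet":
        return cls(np.linspace(x_lo, x_hi, Q), scheme="uniform")

    @classmethod
    def halton(cls, x_lo: float, x_hi: float, Q: int = 41) -> "NodeSet":
        """Deterministic low-discrepancy nodes (endpoints appended so the
        domain boundary is always collocated)."""
        from scipy.stats import qmc

        h = qmc.Halton(d=1, scramble=False).random(Q - 2).ravel()
        pts = np.concatenate([[0.0, 1.0], h])
        pts = x_lo + (x_hi - x_lo) * np.unique(pts)
        return cls(pts, scheme="halton")


@dataclass(frozen=True)
class KernelConfig:
    """Kernel family, shape parameter and solve options.

    ``eps=None`` selects the spacing-based default ``1 / (2 * mean spacing)``.
    """

    kind: str = "gaussian"
    eps: float | None = None
    poly_tail: bool = True
    ridge: float = 1e-12

    def resolve_eps(self, nodes: NodeSet) -> float:
        if self.eps is not None:
            if not self.eps > 0:
                raise ValueError("shape parameter eps must be positive")
            return float(self.eps)
        if nodes.Q < 2:
            raise ValueError("spacing-based eps needs at least 2 nodes")
        return 1.0 / (2.0 * nodes.spacing)


def _kernel_matrix(kind: str, eps: float, r: np.ndarray) -> np.ndarray:
    if kind == "gaussian":
        return np.exp(-eps * r**2)
    if kind == "multiquadric":
        return np.sqrt(1.0 + (eps * r) ** 2)
    raise ValueError(f"unknown kernel {kind!r}")


@dataclass(frozen=True)
class RBFInterpolant:
    """Fitted kernel expansion over a node set.

    ``coeffs`` holds the ``Q`` kernel weights; ``tail`` the (constant,
    linear) polynomial coefficients when the tail is enabled.  Evaluation
    points outside ``[x_lo, x_hi]`` are clamped to the domain before
    evaluation (kernel extrapolation is unstable).
    """

    nodes: NodeSet
    kernel: KernelConfig
    eps: float
    coeffs: np.ndarray
    tail: np.ndarray
    values: np.ndarray
    x_lo: float
    x_hi: float

    def __call__(self, x):
        return eval_rbf(self, x)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": self.nodes.points.tolist(),
                "scheme": self.nodes.scheme,
                "kernel": self.kernel.kind,
                "eps": self.eps,
                "poly_tail": self.kernel.poly_tail,
                "ridge": self.kernel.ridge,
                "coeffs": self.coeffs.tolist(),
                "tail": self.tail.tolist(),
                "values": self.values.tolist(),
                "domain": [self.x_lo, self.x_hi],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RBFInterpolant":
        d = json.loads(text)
        nodes = NodeSet(np.asarray(d["nodes"]), scheme=d["scheme"])
        kernel = KernelConfig(kind=d["kernel"], eps=d["eps"],
                              poly_tail=d["poly_tail"], ridge=d["ridge"])
        return cls(
            nodes=nodes, kernel=kernel, eps=float(d["eps"]),
            coeffs=np.asarray(d["coeffs"]), tail=np.asarray(d["tail"]),
            values=np.asarray(d["values"]),
            x_lo=d["domain"][0], x_hi=d["domain"][1],
        )


def fit_rbf(
    nodes: NodeSet,
    values: Sequence[float],
    kernel: KernelConfig = KernelConfig(),
    x_lo: float | None = None,
    x_hi: float | None = None,
) -> RBFInterpolant:
    """Solve the symmetric collocation system for the kernel weights.

    With the polynomial tail the augmented saddle system

        [A + ridge I, P; P^T, 0] [lam; g] = [values; 0]

    is solved, where ``A_jk = phi(|y_j - y_k|)`` and ``P = [1, y]``.  A
    singular system (beyond what the ridge term rescues) raises a numerical
    error with a diagnostic.
    """
    vals = np.asarray(values, dtype=float)
    Q = nodes.Q
    if vals.shape != (Q,):
        raise ValueError(f"expected {Q} values, got shape {vals.shape}")
    eps = kernel.resolve_eps(nodes)
    y = nodes.points
    A = _kernel_matrix(kernel.kind, eps, np.abs(y[:, None] - y[None, :]))
    A = A + kernel.ridge * np.eye(Q)
    if kernel.poly_tail:
        P = np.stack([np.ones(Q), y], axis=1)
        G = np.block([[A, P], [P.T, np.zeros((2, 2))]])
        rhs = np.concatenate([vals, np.zeros(2)])
    else:
        G, rhs = A, vals
    try:
        sol = scipy.linalg.solve(G, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise np.linalg.LinAlgError(
            f"singular collocation system (Q={Q}, kernel={kernel.kind}, "
            f"eps={eps:g}, ridge={kernel.ridge:g}): {exc}"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError(
            f"non-finite collocation solution (Q={Q}, eps={eps:g}); "
            "increase ridge or reduce the shape parameter"
        )
    coeffs = sol[:Q]
    tail = sol[Q:] if kernel.poly_tail else np.zeros(2)
    if x_lo is None:
        x_lo = float(np.min(y))
    if x_hi is None:
        x_hi = float(np.max(y))
    return RBFInterpolant(nodes=nodes, kernel=kernel, eps=eps, coeffs=coeffs,
                          tail=tail, values=vals, x_lo=x_lo, x_hi=x_hi)


def eval_rbf_deriv(interp: RBFInterpolant, points, order: int = 1):
    """Analytic derivative of the kernel expansion (order 1 or 2).

    Queries are clamped to the domain like :func:`eval_rbf`; note the
    derivative of the clamped extension is one-sided at the boundary.
    """
    x = np.clip(np.asarray(points, dtype=float), interp.x_lo, interp.x_hi)
    scalar = x.ndim == 0
    xf = np.atleast_1d(x).ravel()
    diff = xf[:, None] - interp.nodes.points[None, :]
    eps = interp.eps
    if interp.kernel.kind == "gaussian":
        phi = np.exp(-eps * diff**2)
        if order == 1:
            K = -2.0 * eps * diff * phi
        elif order == 2:
            K = (4.0 * eps**2 * diff**2 - 2.0 * eps) * phi
        else:
            raise ValueError("order must be 1 or 2")
    elif interp.kernel.kind == "multiquadric":
        phi = np.sqrt(1.0 + (eps * diff) ** 2)
        if order == 1:
            K = eps**2 * diff / phi
        elif order == 2:
            K = eps**2 / phi - eps**4 * diff**2 / phi**3
        else:
            raise ValueError("order must be 1 or 2")
    else:  # pragma: no cover
        raise ValueError(f"unknown kernel {interp.kernel.kind!r}")
    out = K @ interp.coeffs
    if order == 1:
        out = out + interp.tail[1]
    out = out.reshape(np.atleast_1d(x).shape)
    return float(out[0]) if scalar else out


def interpolation_matrix(nodes: NodeSet, kernel: KernelConfig, points,
                         x_lo: float, x_hi: float) -> np.ndarray:
    """Cardinal interpolation weights ``W`` with ``s(points) = W @ values``.

    Row ``m`` holds the weights that map node values to the interpolant's
    value at ``points[m]`` (points clamped to the domain first).  Used by the
    solver's policy-evaluation step, where the continuation operator must be
    expressed as a linear map on node values.
    """
    eps = kernel.resolve_eps(nodes)
    y = nodes.points
    Q = nodes.Q
    A = _kernel_matrix(kernel.kind, eps, np.abs(y[:, None] - y[None, :]))
    A = A + kernel.ridge * np.eye(Q)
    x = np.clip(np.asarray(points, dtype=float).ravel(), x_lo, x_hi)
    K = _kernel_matrix(kernel.kind, eps, np.abs(x[:, None] - y[None, :]))
    if kernel.poly_tail:
        P = np.stack([np.ones(Q), y], axis=1)
        G = np.block([[A, P], [P.T, np.zeros((2, 2))]])
        E = np.hstack([K, np.stack([np.ones(x.size), x], axis=1)])
        # columns of G^{-1}[:, :Q] give coefficients for unit node values
        return E @ scipy.linalg.solve(G, np.eye(Q + 2)[:, :Q])
    return K @ scipy.linalg.solve(A, np.eye(Q))


def eval_rbf(interp: RBFInterpolant, points):
    """Evaluate the kernel expansion; off-domain queries are clamped."""
    x = np.clip(np.asarray(points, dtype=float), interp.x_lo, interp.x_hi)
    scalar = x.ndim == 0
    xf = np.atleast_1d(x).ravel()
    K = _kernel_matrix(interp.kernel.kind, interp.eps,
                       np.abs(xf[:, None] - interp.nodes.points[None, :]))
    out = K @ interp.coeffs + interp.tail[0] + interp.tail[1] * xf
    out = out.reshape(np.atleast_1d(x).shape)
    return float(out[0]) if scalar else out
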