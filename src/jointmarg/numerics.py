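"""Shared numerical kernels: quadrature, finite differences, sampling, root finding.

All quadrature constants are embedded as literals so results are bit-stable
across platforms. Random-number generation is organised as one seed per
top-level call, split into per-subject substreams keyed by subject index so
that results do not depend on iteration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "QuadratureRule",
    "gk15_rule",
    "gauss_hermite_rule",
    "gk15_integrate",
    "central_difference_row",
    "cumulative_row",
    "sample_mvnormal",
    "solve_increasing",
    "subject_rng",
    "NoRootInBracketError",
    "NonPSDCovarianceError",
]

# 15-point Kronrod extension of the 7-point Gauss rule on [-1, 1]
# (published constants; not recomputed at runtime).
_GK15_NODES_POS = np.array(
    [
        0.991455371120813,
        0.949107912342759,
        0.864864423359769,
        0.741531185599394,
        0.586087235467691,
        0.405845151377397,
        0.207784955007898,
        0.000000000000000,
    ]
)
_GK15_WEIGHTS_POS = np.array(
    [
        0.022935322010529,
        0.063092092629979,
        0.104790010322250,
        0.140653259715525,
        0.169004726639267,
        0.190350578064785,
        0.204432940075298,
        0.209482141084728,
    ]
)

GK15_NODES = np.concatenate([-_GK15_NODES_POS[:-1], _GK15_NODES_POS[::-1]])
GK15_WEIGHTS = np.concatenate([_GK15_WEIGHTS_POS[:-1], _GK15_WEIGHTS_POS[::-1]])


class NoRootInBracketError(RuntimeError):
    """The monotone function never reaches the target inside the bracket."""


class NonPSDCovarianceError(ValueError):
    """Covariance matrix has a negative eigenvalue."""


@dataclass(frozen=True)
class QuadratureRule:
    """A fixed quadrature rule: nodes, weights and a kind tag."""

    nodes: np.ndarray
    weights: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.weights):
            raise ValueError("nodes and weights must have equal length")
        if self.kind == "gauss_kronrod_15" and len(self.nodes) != 15:
            raise ValueError("gauss_kronrod_15 rule must have 15 nodes")
        if self.kind == "gauss_hermite" and np.any(self.weights <= 0):
            raise ValueError("gauss_hermite weights must be positive")


def gk15_rule() -> QuadratureRule:
    """The 15-point Gauss-Kronrod rule on [-1, 1]."""
    return QuadratureRule(GK15_NODES.copy(), GK15_WEIGHTS.copy(), "gauss_kronrod_15")


def gauss_hermite_rule(order: int) -> QuadratureRule:
    """Gauss-Hermite rule of the given order (weight exp(-x^2) on the real line)."""
    nodes, weights = special.roots_hermite(order)
    return QuadratureRule(nodes, weights, "gauss_hermite")


def gk15_points(a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Abscissas and weights of GK15 mapped onto [a, b]."""
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    return half * GK15_NODES + mid, half * GK15_WEIGHTS


def gk15_integrate(f: Callable[[float], float], a: float, b: float) -> float:
    """Integrate ``f`` over ``[a, b]`` with the fixed 15-point Gauss-Kronrod rule.

    Exact for polynomials of degree <= 22.
    """
    if a > b:
        raise ValueError(f"invalid interval: a={a} > b={b}")
    pts, wts = gk15_points(a, b)
    vals = np.array([f(t) for t in pts], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = pts[~np.isfinite(vals)]
        raise ValueError(f"integrand non-finite at quadrature node(s) {bad}")
    return float(wts @ vals)


def central_difference_row(
    x_fun: Callable[[float], np.ndarray],
    t: float,
    eps: float = 1e-3,
    lower_bound: float | None = None,
) -> np.ndarray:
    """Componentwise central-difference derivative of a time-to-row map.

    Uses ``(x(t + eps) - x(t - eps)) / (2 eps)``; exact for components that are
    polynomial of degree <= 2 in ``t``. If ``t - eps`` would fall below
    ``lower_bound``, falls back to a one-sided forward difference with a warning.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if lower_bound is not None and t - eps < lower_bound:
        warnings.warn(
            f"t - eps = {t - eps} below domain lower bound {lower_bound}; "
            "using one-sided forward difference",
            stacklevel=2,
        )
        x0 = np.asarray(x_fun(t), dtype=float)
        x1 = np.asarray(x_fun(t + eps), dtype=float)
        return (x1 - x0) / eps
    x_hi = np.asarray(x_fun(t + eps), dtype=float)
    x_lo = np.asarray(x_fun(t - eps), dtype=float)
    return (x_hi - x_lo) / (2.0 * eps)


def cumulative_row(x_fun: Callable[[float], np.ndarray], t: float) -> np.ndarray:
    """Componentwise GK15 integral of a time-to-row map over ``[0, t]``."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        return np.zeros_like(np.asarray(x_fun(0.0), dtype=float))
    pts, wts = gk15_points(0.0, t)
    rows = np.array([np.asarray(x_fun(s), dtype=float) for s in pts])
    if not np.all(np.isfinite(rows)):
        raise ValueError("row function non-finite at a quadrature node")
    return wts @ rows


def _check_psd(cov: np.ndarray) -> None:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise NonPSDCovarianceError("covariance matrix is not symmetric")
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig < -1e-10 * max(1.0, float(np.abs(cov).max())):
        raise NonPSDCovarianceError(
            f"covariance matrix is not PSD (smallest eigenvalue {min_eig:g})"
        )


def sample_mvnormal(
    mean: Sequence[float],
    cov: np.ndarray,
    count: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``count`` multivariate-normal samples, reproducibly.

    ``seed`` may be an integer or an existing Generator (for substreams).
    The covariance is factored by eigendecomposition so exactly-singular
    (including zero) matrices are allowed.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    _check_psd(cov)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eigval, eigvec = np.linalg.eigh(cov)
    eigval = np.clip(eigval, 0.0, None)
    root = eigvec * np.sqrt(eigval)
    z = rng.standard_normal((count, len(mean)))
    return mean + z @ root.T


def subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Per-subject substream: deterministic in (seed, subject index) only."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(subject_index))))


def solve_increasing(
    fn: Callable[[float], float],
    target: float,
    bracket: tuple[float, float],
    tol: float = 1e-10,
) -> float:
    """Solve ``fn(t) = target`` for a continuous nondecreasing ``fn`` on a bracket.

    Raises :class:`NoRootInBracketError` when ``fn(hi) < target`` (the caller
    typically censors administratively in that case).
    """
    lo, hi = bracket
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError(f"invalid bracket {bracket}")
    f_lo = fn(lo) - target
    if f_lo > 1e-12:
        raise ValueError(f"fn(lo)={fn(lo)} exceeds target {target}")
    if f_lo >= 0:
        return lo
    f_hi = fn(hi) - target
    if f_hi < 0:
        raise NoRootInBracketError(
            f"fn({hi})={fn(hi)} below target {target}: no root in bracket"
        )
    return float(optimize.brentq(lambda t: fn(t) - target, lo, hi, xtol=tol))
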