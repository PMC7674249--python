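"""Monte-Carlo marginalization of subject-specific hazards and the
least-squares projection onto marginal coefficients.

The marginal log hazard at time t is

    log h^M(t) = log [ E_b{ h(t|b) S(t|b) } / E_b{ S(t|b) } ],

approximated by Monte Carlo over random-effect draws, with the conditional
survival computed by the 15-point Gauss-Kronrod rule. Stacking marginal log
hazards at all longitudinal and observed times and regressing them on
[W_h0 | W | X beta] yields the marginal parameter vector
(gamma_h0^M, gamma^M, alpha^M). A deterministic Gauss-Hermite evaluation of
the same ratio of integrals is provided as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from . import numerics
from .model_core import (
    Dataset,
    JointModelSpec,
    ParameterSet,
    StackedDesign,
    TIME_FLOOR,
    build_stacked_design,
    hazard_design,
    log_conditional_hazard,
)

__all__ = [
    "MarginalizationConfig",
    "MarginalParameters",
    "conditional_survival",
    "marginal_log_hazard",
    "marginal_log_hazard_oracle",
    "project_marginal",
    "marginal_coefs",
]


@dataclass(frozen=True)
class MarginalizationConfig:
    """Monte-Carlo settings: numerator draws G, denominator draws K, seed.

    ``draw_sharing="common"`` reuses the numerator draws in the denominator
    (variance reduction; also makes the marginal hazard an exact weighted mean
    of the conditional hazards). ``survival_horizon`` selects whether the
    survival factor inside the ratio is evaluated at the row time (default) or
    literally at the subject's observed time.
    """

    G: int = 5000
    K: int = 5000
    seed: int = 0
    draw_sharing: str = "independent"
    survival_horizon: str = "row_time"

    def __post_init__(self) -> None:
        if self.G < 1 or self.K < 1:
            raise ValueError("G and K must be >= 1")
        if self.draw_sharing not in ("independent", "common"):
            raise ValueError(f"unknown draw_sharing {self.draw_sharing!r}")
        if self.survival_horizon not in ("row_time", "observed_time"):
            raise ValueError(f"unknown survival_horizon {self.survival_horizon!r}")


@dataclass(frozen=True)
class MarginalParameters:
    """Marginal coefficients (gamma_h0^M, gamma^M, alpha^M)."""

    gamma_h0_M: np.ndarray
    gamma_M: np.ndarray
    alpha_M: float

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.gamma_h0_M, self.gamma_M, [self.alpha_M]])

    def to_dict(self) -> dict:
        return {
            "gamma_h0_M": np.asarray(self.gamma_h0_M).tolist(),
            "gamma_M": np.asarray(self.gamma_M).tolist(),
            "alpha_M": float(self.alpha_M),
        }

    @staticmethod
    def from_dict(d: Mapping) -> "MarginalParameters":
        return MarginalParameters(
            np.asarray(d["gamma_h0_M"], dtype=float),
            np.asarray(d["gamma_M"], dtype=float),
            float(d["alpha_M"]),
        )


# ---------------------------------------------------------------------------
# Conditional building blocks (vectorized over times and draws)


def _log_hazard_draws(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    times: np.ndarray,
    b: np.ndarray,
) -> np.ndarray:
    """log h(t|b) for times (m,) x draws (B, d) -> (m, B)."""
    wh0, w, xstar, zstar = hazard_design(spec, covariates, times)
    base = wh0 @ params.gamma_h0 + w @ params.gamma + params.alpha * (xstar @ params.beta)
    return base[:, None] + params.alpha * (zstar @ b.T)


def _log_survival_draws(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    times: np.ndarray,
    b: np.ndarray,
) -> np.ndarray:
    """log S(t|b) = -int_0^t h(u|b) du for times (m,) x draws (B, d) -> (m, B)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    m = len(times)
    half = 0.5 * times  # P = t/2
    pts = half[:, None] * (numerics.GK15_NODES[None, :] + 1.0)  # (m, 15)
    wts = half[:, None] * numerics.GK15_WEIGHTS[None, :]
    logh = _log_hazard_draws(spec, params, covariates, pts.ravel(), b).reshape(m, 15, -1)
    with np.errstate(over="ignore"):
        cumhaz = np.einsum("mu,muB->mB", wts, np.exp(logh))
    return -cumhaz


def conditional_survival(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    b: Sequence[float],
    t: float,
) -> float:
    """S(t|b) via the 15-point Gauss-Kronrod approximation of the cumulative hazard."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 1.0
    b = np.atleast_2d(np.asarray(b, dtype=float))
    return float(np.exp(_log_survival_draws(spec, params, covariates, np.array([t]), b)[0, 0]))


# ---------------------------------------------------------------------------
# Marginal log hazard: Monte Carlo and quadrature oracle


def _mc_marginal_log_hazard_rows(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    times: np.ndarray,
    config: MarginalizationConfig,
    rng: np.random.Generator,
    observed_time: float | None = None,
) -> np.ndarray:
    """Marginal log hazards at several times for one subject, sharing one draw set."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    d = params.dim_b
    b_num = numerics.sample_mvnormal(np.zeros(d), params.Sigma_b, config.G, rng)
    if config.draw_sharing == "common" and config.K == config.G:
        b_den = b_num
    else:
        b_den = numerics.sample_mvnormal(np.zeros(d), params.Sigma_b, config.K, rng)

    if config.survival_horizon == "observed_time":
        if observed_time is None:
            raise ValueError("observed_time required for survival_horizon='observed_time'")
        s_times = np.full_like(times, float(observed_time))
    else:
        s_times = times

    logh = _log_hazard_draws(spec, params, covariates, times, b_num)  # (m, G)
    logS_num = _log_survival_draws(spec, params, covariates, s_times, b_num)
    logS_den = (
        logS_num
        if b_den is b_num
        else _log_survival_draws(spec, params, covariates, s_times, b_den)
    )
    log_num = logsumexp(logh + logS_num, axis=1) - np.log(config.G)
    log_den = logsumexp(logS_den, axis=1) - np.log(config.K)
    if np.any(~np.isfinite(log_den)):
        raise FloatingPointError(
            "all survival draws underflowed to zero; marginal hazard undefined"
        )
    return log_num - log_den


def marginal_log_hazard(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    t: float,
    config: MarginalizationConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo marginal log hazard log[E{hS}/E{S}] at a single time."""
    if t <= 0:
        raise ValueError("t must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return float(
        _mc_marginal_log_hazard_rows(
            spec, params, covariates, np.array([t]), config, rng, observed_time=t
        )[0]
    )


def _gh_draw_set(Sigma_b: np.ndarray, gh_order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite 'draws' and log weights for integrating against N(0, Sigma_b)."""
    d = Sigma_b.shape[0]
    if d > 2:
        raise ValueError("quadrature oracle supports dim(b) <= 2 only")
    rule = numerics.gauss_hermite_rule(gh_order)
    eigval, eigvec = np.linalg.eigh(Sigma_b)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    if d == 1:
        x = rule.nodes[:, None]
        logw = np.log(rule.weights) - 0.5 * np.log(np.pi)
    else:
        x1, x2 = np.meshgrid(rule.nodes, rule.nodes, indexing="ij")
        x = np.column_stack([x1.ravel(), x2.ravel()])
        w1, w2 = np.meshgrid(rule.weights, rule.weights, indexing="ij")
        logw = np.log(w1.ravel()) + np.log(w2.ravel()) - np.log(np.pi)
    b = np.sqrt(2.0) * x @ root.T
    return b, logw


def marginal_log_hazard_oracle(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    t: float,
    gh_order: int = 60,
    observed_time: float | None = None,
) -> float:
    """Deterministic Gauss-Hermite evaluation of the marginal log hazard.

    Independent of the Monte-Carlo path; supports 1- and 2-dimensional random
    effects.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if np.allclose(params.Sigma_b, 0.0):
        return log_conditional_hazard(spec, params, covariates, np.zeros(params.dim_b), t)
    b, logw = _gh_draw_set(params.Sigma_b, gh_order)
    times = np.array([t])
    s_time = np.array([float(observed_time)]) if observed_time is not None else times
    logh = _log_hazard_draws(spec, params, covariates, times, b)[0]
    logS = _log_survival_draws(spec, params, covariates, s_time, b)[0]
    return float(logsumexp(logw + logh + logS) - logsumexp(logw + logS))


# ---------------------------------------------------------------------------
# Projection


def project_marginal(
    stacked: StackedDesign, logH: np.ndarray, q_h0: int | None = None
) -> MarginalParameters:
    """Least-squares projection theta^M = (X'X)^{-1} X' logH^M.

    Raises on rank deficiency (no silent pseudo-inverse) and verifies residual
    orthogonality of the solution.
    """
    X = stacked.matrix
    logH = np.asarray(logH, dtype=float)
    if len(logH) != X.shape[0]:
        raise ValueError(f"logH has length {len(logH)}, expected {X.shape[0]}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("stacked design is rank deficient; projection unidentified")
    # Householder QR (bitwise run-to-run reproducible, unlike the SVD-based lstsq)
    Q, R = np.linalg.qr(X)
    theta = solve_triangular(R, Q.T @ logH)
    resid = logH - X @ theta
    ortho = np.abs(X.T @ resid).max() / max(1.0, np.abs(X.T @ logH).max())
    if ortho > 1e-8:
        raise np.linalg.LinAlgError(f"projection residual not orthogonal (rel. {ortho:g})")
    q = stacked.q_h0 if q_h0 is None else q_h0
    if q is None:
        raise ValueError("q_h0 block size unknown; pass q_h0 explicitly")
    return MarginalParameters(
        gamma_h0_M=theta[:q], gamma_M=theta[q:-1], alpha_M=float(theta[-1])
    )


# ---------------------------------------------------------------------------
# Full pipeline


def marginal_log_hazard_vector(
    spec: JointModelSpec,
    params: ParameterSet,
    dataset: Dataset,
    stacked: StackedDesign,
    config: MarginalizationConfig,
    method: str = "mc",
    gh_order: int = 60,
) -> np.ndarray:
    """Marginal log hazards at every stacked row (grouped per subject).

    Monte-Carlo draws use fresh per-subject substreams keyed by the subject's
    position in the survival table, so results are independent of row order.
    """
    surv = dataset.survival
    t_by_id = dict(zip(surv["id"], surv["time"]))
    pos_by_id = {sid: k for k, sid in enumerate(surv["id"])}
    cov_by_id = {
        rec["id"]: {k: v for k, v in rec.items() if k not in ("time", "event")}
        for rec in surv.to_dict("records")
    }

    row_ids = [r[0] for r in stacked.row_index]
    row_times = np.array([max(r[1], TIME_FLOOR) for r in stacked.row_index])
    logH = np.empty(len(row_ids))

    order = {}
    for k, sid in enumerate(row_ids):
        order.setdefault(sid, []).append(k)

    for sid, idx in order.items():
        times = row_times[idx]
        cov = cov_by_id[sid]
        t_obs = max(float(t_by_id[sid]), TIME_FLOOR)
        if method == "mc":
            rng = numerics.subject_rng(config.seed, pos_by_id[sid])
            vals = _mc_marginal_log_hazard_rows(
                spec, params, cov, times, config, rng, observed_time=t_obs
            )
        elif method == "oracle":
            horizon = t_obs if config.survival_horizon == "observed_time" else None
            vals = np.array(
                [
                    marginal_log_hazard_oracle(
                        spec, params, cov, t, gh_order=gh_order, observed_time=horizon
                    )
                    for t in times
                ]
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        logH[idx] = vals
    return logH


def marginal_coefs(
    fit,
    dataset: Dataset,
    config: MarginalizationConfig,
    params: ParameterSet | None = None,
    beta_for_design: np.ndarray | None = None,
    include_censored: bool = True,
    method: str = "mc",
    gh_order: int = 60,
) -> MarginalParameters:
    """End-to-end marginal coefficients: stack, marginalize, project.

    ``fit`` is anything exposing ``.spec`` and ``.params`` (a FitResult).
    ``params`` overrides the parameter set (used by the SE scheme with drawn
    parameters); ``beta_for_design`` overrides the beta used in the stacked
    design's last column.
    """
    spec: JointModelSpec = fit.spec
    p: ParameterSet = params if params is not None else fit.params
    design_params = (
        p if beta_for_design is None else replace_beta(p, np.asarray(beta_for_design))
    )
    stacked = build_stacked_design(spec, design_params, dataset, include_censored=include_censored)
    logH = marginal_log_hazard_vector(
        spec, p, dataset, stacked, config, method=method, gh_order=gh_order
    )
    return project_marginal(stacked, logH)


def replace_beta(params: ParameterSet, beta: np.ndarray) -> ParameterSet:
    return ParameterSet(
        gamma_h0=params.gamma_h0,
        beta=beta,
        gamma=params.gamma,
        alpha=params.alpha,
        sigma2=params.sigma2,
        Sigma_b=params.Sigma_b,
    )
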