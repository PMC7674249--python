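"""Overall treatment-effect curves (subject-specific and marginal), weighted
averages over time, and the simulation-based standard-error scheme.

The SS curve is exp{W_bar gamma^SS + alpha^SS X_bar(t) beta}; the marginal
curve uses (gamma^M, alpha^M) with the same beta. Uncertainty comes from L
parameter draws on the unconstrained scale of the fitted covariance, each
pushed through the full marginalization pipeline; SEs and bands are sample
SDs and percentiles over the resulting replicates.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from . import numerics
from .marginalize import (
    MarginalizationConfig,
    MarginalParameters,
    marginal_coefs,
)
from .model_core import Dataset, TreatmentContrast
from .fit import FitResult

__all__ = [
    "EffectCurve",
    "WeightFunction",
    "MarginalUncertainty",
    "effect_curve_ss",
    "effect_curve_marginal",
    "weighted_effect",
    "uniform_weight",
    "survival_weight",
    "marginal_se",
    "curve_band",
    "UnnormalizedWeightError",
]


class UnnormalizedWeightError(ValueError):
    """The weight function does not integrate to 1 over [0, t0]."""


@dataclass(frozen=True)
class EffectCurve:
    """Hazard-ratio curve on a time grid, optionally with a pointwise band."""

    times: np.ndarray
    hr: np.ndarray
    flavor: str
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.hr) <= 0):
            raise ValueError("hazard ratios must be positive")


@dataclass(frozen=True)
class WeightFunction:
    """Normalized weight over [0, t0] for averaging the log effect curve."""

    kind: str
    t0: float
    density: Callable[[float], float]
    renormalize: bool = False


def uniform_weight(t0: float) -> WeightFunction:
    """The normalized uniform weight Omega = 1/t0 on [0, t0]."""
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    return WeightFunction(kind="uniform", t0=float(t0), density=lambda t: 1.0 / t0)


def survival_weight(dataset: Dataset, t0: float) -> WeightFunction:
    """Weight proportional to the pooled Kaplan-Meier survival estimate.

    Puts more mass where more subjects remain at risk; normalized by GK15.
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(dataset.survival["time"], dataset.survival["event"])
    raw = lambda t: float(km.predict(min(t, float(dataset.survival["time"].max()))))
    norm = numerics.gk15_integrate(raw, 0.0, t0)
    return WeightFunction(kind="survival_weighted", t0=float(t0), density=lambda t: raw(t) / norm)


def _loghr_fn(gamma: np.ndarray, alpha: float, beta: np.ndarray, contrast: TreatmentContrast):
    w_term = float(contrast.W_bar @ np.atleast_1d(gamma))

    def loghr(t: float) -> float:
        return w_term + alpha * float(contrast.X_bar(t) @ beta)

    return loghr


def effect_curve_ss(
    fit: FitResult, contrast: TreatmentContrast, times: Sequence[float]
) -> EffectCurve:
    """Subject-specific overall treatment effect exp{W_bar gamma + alpha X_bar(t) beta}."""
    times = np.asarray(times, dtype=float)
    loghr = _loghr_fn(fit.params.gamma, fit.params.alpha, fit.params.beta, contrast)
    return EffectCurve(times=times, hr=np.exp([loghr(t) for t in times]), flavor="SS")


def effect_curve_marginal(
    marginal: MarginalParameters,
    fit: FitResult,
    contrast: TreatmentContrast,
    times: Sequence[float],
) -> EffectCurve:
    """Marginal overall treatment effect; beta is taken from the fit."""
    times = np.asarray(times, dtype=float)
    loghr = _loghr_fn(marginal.gamma_M, marginal.alpha_M, fit.params.beta, contrast)
    return EffectCurve(times=times, hr=np.exp([loghr(t) for t in times]), flavor="marginal")


def weighted_effect(loghr: Callable[[float], float], weight: WeightFunction) -> float:
    """phi(t0) = exp{ int_0^t0 log hr(t) Omega(t) dt } via GK15.

    Raises :class:`UnnormalizedWeightError` when the weight does not integrate
    to 1, unless it is a custom weight with ``renormalize=True``.
    """
    total = numerics.gk15_integrate(weight.density, 0.0, weight.t0)
    scale = 1.0
    if abs(total - 1.0) > 1e-6:
        if weight.kind == "custom" and weight.renormalize:
            scale = 1.0 / total
        else:
            raise UnnormalizedWeightError(
                f"weight integrates to {total:g} over [0, {weight.t0}], not 1"
            )
    val = numerics.gk15_integrate(lambda t: loghr(t) * weight.density(t) * scale, 0.0, weight.t0)
    return float(np.exp(val))


# ---------------------------------------------------------------------------
# Simulation-based standard errors


@dataclass(frozen=True)
class MarginalUncertainty:
    """L replicate draws of theta^M with sample SDs and percentile CIs."""

    replicates: np.ndarray  # (L, q_h0 + q_gamma + 1)
    q_h0: int
    ci_level: float = 0.95
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.replicates) < 2:
            raise ValueError("need at least 2 replicates for SDs")

    @property
    def se(self) -> np.ndarray:
        # centred on the first replicate so identical replicates give exactly 0
        return (self.replicates - self.replicates[0]).std(axis=0, ddof=1)

    @property
    def alpha_M_draws(self) -> np.ndarray:
        return self.replicates[:, -1]

    @property
    def gamma_M_draws(self) -> np.ndarray:
        return self.replicates[:, self.q_h0 : -1]

    def ci(self, level: float | None = None) -> np.ndarray:
        """Percentile CI per coefficient, shape (2, dim)."""
        level = self.ci_level if level is None else level
        lo = 50.0 * (1.0 - level)
        return np.percentile(self.replicates, [lo, 100.0 - lo], axis=0)


def _seed_from_draw(base_seed: int, draw_bytes: bytes) -> int:
    """Deterministic MC seed for one parameter draw (identical draws share it)."""
    return int(np.random.SeedSequence((int(base_seed), zlib.crc32(draw_bytes))).generate_state(1)[0])


def marginal_se(
    fit: FitResult,
    dataset: Dataset,
    config: MarginalizationConfig,
    L: int = 200,
    ci_level: float = 0.95,
    beta_in_design: str = "draw",
    include_censored: bool = True,
) -> MarginalUncertainty:
    """Monte-Carlo SE scheme for the marginal coefficients.

    Each of the L replicates draws a full parameter vector from
    N(theta_hat, Var) on the unconstrained scale (guaranteeing a valid
    sigma^2 and Sigma_b), recomputes the marginal log hazards under the drawn
    parameters, and reprojects. ``beta_in_design`` controls whether the drawn
    or the ML beta enters the stacked design's last column.

    Each replicate's random-effect draw seed is derived deterministically from
    the drawn parameter vector, so distinct draws refresh the Monte-Carlo
    noise (which then contributes to the replicate spread, as in rerunning the
    scheme from scratch) while identical draws — in particular every replicate
    when Var = 0 — reuse identical noise and yield exactly identical
    replicates.
    """
    if fit.vcov_unconstrained is None:
        raise ValueError("fit has no parameter covariance (not converged?)")
    if beta_in_design not in ("draw", "mle"):
        raise ValueError(f"unknown beta_in_design {beta_in_design!r}")

    theta_hat = fit.transform.pack(fit.params)
    V = 0.5 * (fit.vcov_unconstrained + fit.vcov_unconstrained.T)
    eigval, eigvec = np.linalg.eigh(V)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))

    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 0x5E)))
    reps: list[np.ndarray] = []
    dropped = 0
    cache: dict[bytes, np.ndarray] = {}  # identical draws (e.g. Var = 0) computed once
    for l in range(L):
        z = rng.standard_normal(len(theta_hat))
        theta_star = theta_hat + root @ z
        key = theta_star.tobytes()
        if key in cache:
            reps.append(cache[key])
            continue
        params_star = fit.transform.unpack(theta_star)
        cfg_l = replace(config, seed=_seed_from_draw(config.seed, key))
        try:
            m = marginal_coefs(
                fit,
                dataset,
                cfg_l,
                params=params_star,
                beta_for_design=fit.params.beta if beta_in_design == "mle" else None,
                include_censored=include_censored,
            )
            theta_m = m.theta
            if not np.all(np.isfinite(theta_m)):
                raise FloatingPointError("non-finite replicate")
            cache[key] = theta_m
            reps.append(theta_m)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            dropped += 1
            warnings.warn(f"dropped SE replicate {l}: {exc}")
    if dropped > 0.05 * L:
        raise RuntimeError(f"{dropped}/{L} SE replicates dropped (> 5%)")
    return MarginalUncertainty(
        replicates=np.array(reps), q_h0=fit.spec.bh_basis.size, ci_level=ci_level,
        n_dropped=dropped,
    )


def curve_band(
    uncertainty: MarginalUncertainty,
    fit: FitResult,
    contrast: TreatmentContrast,
    times: Sequence[float],
    marginal: MarginalParameters | None = None,
    ci_level: float | None = None,
) -> EffectCurve:
    """Pointwise percentile band of the marginal effect curve over replicates.

    The central curve is the point estimate when ``marginal`` is given, else
    the per-time replicate median.
    """
    times = np.asarray(times, dtype=float)
    level = uncertainty.ci_level if ci_level is None else ci_level
    beta = fit.params.beta
    q = uncertainty.q_h0
    log_curves = np.empty((len(uncertainty.replicates), len(times)))
    for r, theta in enumerate(uncertainty.replicates):
        loghr = _loghr_fn(theta[q:-1], float(theta[-1]), beta, contrast)
        log_curves[r] = [loghr(t) for t in times]
    lo_p = 50.0 * (1.0 - level)
    lo, hi = np.percentile(log_curves, [lo_p, 100.0 - lo_p], axis=0)
    if marginal is not None:
        loghr = _loghr_fn(marginal.gamma_M, marginal.alpha_M, beta, contrast)
        center = np.array([loghr(t) for t in times])
    else:
        center = np.median(log_curves, axis=0)
    return EffectCurve(
        times=times, hr=np.exp(center), flavor="marginal", lo=np.exp(lo), hi=np.exp(hi)
    )
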