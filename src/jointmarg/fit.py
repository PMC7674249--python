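"""Maximum-likelihood estimation of the joint model.

The random effects are integrated out with a pseudo-adaptive Gauss-Hermite
product rule: nodes are recentred and rescaled per subject at the empirical
Bayes posterior of a longitudinal-only mixed-model fit, which keeps the
quadrature accurate with few nodes. Optimization runs on an unconstrained
parameterization (log sigma, log-Cholesky of Sigma_b) so every iterate is a
valid parameter set, and the parameter covariance is stored on that same
scale — the simulation-based SE scheme draws there and back-transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from . import numerics
from .model_core import (
    Dataset,
    JointModelSpec,
    ParameterSet,
    TIME_FLOOR,
    _terms_matrix,
    hazard_design,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ParameterTransform",
    "joint_log_likelihood",
    "fit_joint_model",
    "empirical_bayes_modes",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and quadrature settings."""

    n_quad: int = 9
    max_iter: int = 300
    ftol: float = 1e-8
    pgtol: float = 1e-4
    compute_vcov: bool = True


class ParameterTransform:
    """Bijection between a ParameterSet and an unconstrained real vector.

    Layout: [gamma_h0, beta, gamma, alpha, log sigma, log-Cholesky(Sigma_b)]
    where the log-Cholesky block stores the lower triangle row-wise with
    logged diagonal.
    """

    def __init__(self, q_h0: int, p_beta: int, q_gamma: int, dim_b: int):
        self.q_h0, self.p_beta, self.q_gamma, self.dim_b = q_h0, p_beta, q_gamma, dim_b
        self.n_chol = dim_b * (dim_b + 1) // 2
        self.size = q_h0 + p_beta + q_gamma + 1 + 1 + self.n_chol

    def describe(self) -> dict:
        return {
            "layout": ["gamma_h0", "beta", "gamma", "alpha", "log_sigma", "log_chol_Sigma_b"],
            "sizes": [self.q_h0, self.p_beta, self.q_gamma, 1, 1, self.n_chol],
        }

    def pack(self, params: ParameterSet, chol_floor: float = 1e-8) -> np.ndarray:
        d = self.dim_b
        S = params.Sigma_b + np.eye(d) * 0.0
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            eigval, eigvec = np.linalg.eigh(S)
            L = np.linalg.cholesky(
                eigvec @ np.diag(np.clip(eigval, chol_floor**2, None)) @ eigvec.T
            )
        chol = []
        for i in range(d):
            for j in range(i + 1):
                chol.append(np.log(max(L[i, i], chol_floor)) if i == j else L[i, j])
        return np.concatenate(
            [
                params.gamma_h0,
                params.beta,
                params.gamma,
                [params.alpha, 0.5 * np.log(params.sigma2)],
                chol,
            ]
        )

    def unpack(self, theta: np.ndarray) -> ParameterSet:
        theta = np.asarray(theta, dtype=float)
        q, p, g, d = self.q_h0, self.p_beta, self.q_gamma, self.dim_b
        k = 0
        gamma_h0 = theta[k : k + q]; k += q
        beta = theta[k : k + p]; k += p
        gamma = theta[k : k + g]; k += g
        alpha = float(theta[k]); k += 1
        sigma2 = float(np.exp(2.0 * theta[k])); k += 1
        L = np.zeros((d, d))
        for i in range(d):
            for j in range(i + 1):
                L[i, j] = np.exp(theta[k]) if i == j else theta[k]
                k += 1
        return ParameterSet(gamma_h0, beta, gamma, alpha, sigma2, L @ L.T)


@dataclass
class FitResult:
    """Fitted joint model with its unconstrained-scale parameter covariance."""

    params: ParameterSet
    spec: JointModelSpec
    vcov_unconstrained: np.ndarray | None
    transform: ParameterTransform
    loglik: float
    converged: bool
    n_quad: int
    eb_modes: tuple[np.ndarray, np.ndarray] | None = None  # (centers, scale chols)

    @property
    def theta_unconstrained(self) -> np.ndarray:
        return self.transform.pack(self.params)


# ---------------------------------------------------------------------------
# Precomputed arrays


class _FitData:
    """Design arrays for fast vectorized likelihood evaluation."""

    def __init__(self, dataset: Dataset, spec: JointModelSpec):
        surv = dataset.survival
        self.n = len(surv)
        self.ids = surv["id"].to_numpy()
        pos = {sid: k for k, sid in enumerate(self.ids)}
        cov_by_id = {
            rec["id"]: {k: v for k, v in rec.items() if k not in ("time", "event")}
            for rec in surv.to_dict("records")
        }
        self.T = np.maximum(surv["time"].to_numpy(dtype=float), TIME_FLOOR)
        self.delta = surv["event"].to_numpy(dtype=float)

        long = dataset.longitudinal
        self.y = long["y"].to_numpy(dtype=float)
        self.subj = long["id"].map(pos).to_numpy()
        self.n_i = np.bincount(self.subj, minlength=self.n).astype(float)

        # longitudinal (raw) designs
        xl, zl = [], []
        for rec in long.to_dict("records"):
            cov = cov_by_id[rec["id"]]
            t = np.array([rec["time"]])
            xl.append(_terms_matrix(spec.fixed_terms, cov, t)[0])
            zl.append(_terms_matrix(spec.random_terms, cov, t)[0])
        self.Xl = np.array(xl)
        self.Zl = np.array(zl)

        # survival designs at T_i and at the GK nodes of [0, T_i]
        half = 0.5 * self.T
        gk_t = half[:, None] * (numerics.GK15_NODES[None, :] + 1.0)
        self.gk_w = half[:, None] * numerics.GK15_WEIGHTS[None, :]
        wh0_T, xs_T, zs_T, W = [], [], [], []
        wh0_gk, xs_gk, zs_gk = [], [], []
        for i in range(self.n):
            cov = cov_by_id[self.ids[i]]
            a, w, c, d = hazard_design(spec, cov, np.array([self.T[i]]))
            wh0_T.append(a[0]); W.append(w); xs_T.append(c[0]); zs_T.append(d[0])
            a, _, c, d = hazard_design(spec, cov, gk_t[i])
            wh0_gk.append(a); xs_gk.append(c); zs_gk.append(d)
        self.W = np.array(W)
        self.Wh0_T, self.Xs_T, self.Zs_T = np.array(wh0_T), np.array(xs_T), np.array(zs_T)
        self.Wh0_gk, self.Xs_gk, self.Zs_gk = np.array(wh0_gk), np.array(xs_gk), np.array(zs_gk)
        self.dim_b = spec.dim_b
        # per-subject Z'Z for the longitudinal posterior (adaptive recentring)
        self.ZtZ = np.zeros((self.n, self.dim_b, self.dim_b))
        np.add.at(self.ZtZ, self.subj, self.Zl[:, :, None] * self.Zl[:, None, :])


def _integrand_terms(data: _FitData, params: ParameterSet, b_nodes: np.ndarray) -> np.ndarray:
    """Per-subject-per-node log integrand (without the quadrature weights).

    ``b_nodes`` has shape (n, Q, d). Returns (n, Q).
    """
    n, Q, d = b_nodes.shape
    beta, alpha = params.beta, params.alpha
    sigma2 = params.sigma2

    # longitudinal log density
    resid0 = data.y - data.Xl @ beta  # (N,)
    zb = np.einsum("Nd,NQd->NQ", data.Zl, b_nodes[data.subj])  # (N, Q)
    resid = resid0[:, None] - zb
    ll_rows = -0.5 * (_LOG2PI + np.log(sigma2)) - resid**2 / (2.0 * sigma2)
    ll_long = np.zeros((n, Q))
    np.add.at(ll_long, data.subj, ll_rows)

    # survival: delta * log h(T|b) - cumulative hazard
    base_T = data.Wh0_T @ params.gamma_h0 + data.W @ params.gamma + alpha * (data.Xs_T @ beta)
    logh_T = base_T[:, None] + alpha * np.einsum("nd,nQd->nQ", data.Zs_T, b_nodes)
    base_gk = (
        data.Wh0_gk @ params.gamma_h0
        + (data.W @ params.gamma)[:, None]
        + alpha * np.einsum("nup,p->nu", data.Xs_gk, beta)
    )
    logh_gk = base_gk[:, :, None] + alpha * np.einsum("nud,nQd->nuQ", data.Zs_gk, b_nodes)
    cumhaz = np.einsum("nu,nuQ->nQ", data.gk_w, np.exp(logh_gk))
    return ll_long + data.delta[:, None] * logh_T - cumhaz


def _gh_nodes(dim: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    rule = numerics.gauss_hermite_rule(order)
    if dim == 1:
        x = rule.nodes[:, None]
        logw = np.log(rule.weights)
    else:
        grids = np.meshgrid(*([rule.nodes] * dim), indexing="ij")
        x = np.column_stack([g.ravel() for g in grids])
        wg = np.meshgrid(*([rule.weights] * dim), indexing="ij")
        logw = sum(np.log(w.ravel()) for w in wg)
    return x, logw


def _whitening_factor(Sigma_b: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
    """Factor T (d x r) with Sigma_b ~= T T', keeping only eigencomponents
    above ``rel_tol`` of the largest.

    Writing b = T u with u ~ N(0, I_r) turns the random-effects integral into
    a well-conditioned standard-normal one, so near-singular (and exactly
    singular, including zero) covariances integrate accurately instead of
    blowing up through an explicit Sigma_b inverse.
    """
    eigval, eigvec = np.linalg.eigh(Sigma_b)
    thresh = max(float(eigval.max(initial=0.0)) * rel_tol, 1e-14)
    keep = eigval > thresh
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def _posterior_centers_u(
    data: _FitData, params: ParameterSet, T: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject normal approximation (mean, Cholesky scale) to the
    posterior of the whitened random effects u given the longitudinal data.

    Recomputed at every likelihood evaluation so the Gauss-Hermite nodes track
    the current parameters (adaptive quadrature)."""
    r = T.shape[1]
    A = np.einsum("dr,nde,es->nrs", T, data.ZtZ, T) / params.sigma2 + np.eye(r)[None]
    C = np.linalg.inv(A)
    C = 0.5 * (C + np.swapaxes(C, 1, 2))
    resid = data.y - data.Xl @ params.beta
    Ztres = np.zeros((data.n, data.dim_b))
    np.add.at(Ztres, data.subj, data.Zl * resid[:, None])
    mu = np.einsum("nrs,ns->nr", C, Ztres @ T) / params.sigma2
    return mu, np.linalg.cholesky(C + np.eye(r)[None] * 1e-12)


def joint_log_likelihood(
    params: ParameterSet,
    dataset: Dataset,
    spec: JointModelSpec,
    rule: int = 9,
    adaptive: bool = True,
    _data: _FitData | None = None,
) -> float:
    """Observed-data log likelihood with random effects integrated out.

    ``rule`` is the Gauss-Hermite order per (whitened) random-effect
    dimension. The integral runs over u with b = T u, T a reduced-rank square
    root of Sigma_b; with ``adaptive=True`` the rule is recentred at each
    subject's longitudinal posterior under the current parameters. A zero
    ``Sigma_b`` collapses to the b = 0 point mass.
    """
    data = _data if _data is not None else _FitData(dataset, spec)
    T = _whitening_factor(params.Sigma_b)
    r = T.shape[1]
    if r == 0:
        b_nodes = np.zeros((data.n, 1, data.dim_b))
        return float(_integrand_terms(data, params, b_nodes).sum())

    x, logw = _gh_nodes(r, rule)
    if not adaptive:
        # u = sqrt(2) x; the standard-normal prior is absorbed by the GH weight
        b_nodes = (np.sqrt(2.0) * x @ T.T)[None, :, :].repeat(data.n, axis=0)
        logw_full = logw[None, :] - 0.5 * r * np.log(np.pi)
        ll_nq = _integrand_terms(data, params, b_nodes)
        return float(logsumexp(logw_full + ll_nq, axis=1).sum())

    mu, Ls = _posterior_centers_u(data, params, T)
    u_nodes = mu[:, None, :] + np.sqrt(2.0) * np.einsum("Qr,nsr->nQs", x, Ls)
    b_nodes = np.einsum("nQr,dr->nQd", u_nodes, T)
    logdetL = np.log(np.einsum("nrr->nr", Ls).clip(1e-300)).sum(axis=1)
    # importance form: int g(u) du ~= sum_q w_q 2^{r/2} |L| e^{x'x} g(u_q)
    logw_full = (
        logw[None, :]
        + 0.5 * r * np.log(2.0)
        + logdetL[:, None]
        + np.sum(x**2, axis=1)[None, :]
    )
    log_prior_u = -0.5 * (r * _LOG2PI + np.sum(u_nodes**2, axis=2))
    ll_nq = _integrand_terms(data, params, b_nodes) + log_prior_u
    return float(logsumexp(logw_full + ll_nq, axis=1).sum())


# ---------------------------------------------------------------------------
# Two-stage initialization


def _lmm_stage(dataset: Dataset, spec: JointModelSpec, data: _FitData):
    """Longitudinal-only ML fit for starting values."""
    import statsmodels.api as sm

    d = data.dim_b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(data.y, data.Xl, groups=data.subj, exog_re=data.Zl)
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
            beta0 = np.asarray(res.fe_params)
            sigma2_0 = float(res.scale)
            Sigma0 = np.asarray(res.cov_re)
        except Exception:
            beta0, *_ = np.linalg.lstsq(data.Xl, data.y, rcond=None)
            sigma2_0 = float(np.var(data.y - data.Xl @ beta0)) or 1.0
            Sigma0 = np.eye(d) * 0.5 * sigma2_0

    Sigma0 = 0.5 * (Sigma0 + Sigma0.T) + np.eye(d) * 1e-6
    return beta0, sigma2_0, Sigma0


def _survival_stage(dataset: Dataset, spec: JointModelSpec) -> tuple[np.ndarray, float]:
    """Cox fit for gamma init and a crude constant log baseline hazard."""
    surv = dataset.survival
    rate = max(surv["event"].sum(), 0.5) / max(surv["time"].sum(), 1e-8)
    gamma0 = np.zeros(spec.q_gamma)
    try:
        from lifelines import CoxPHFitter

        df = surv[["time", "event", *spec.baseline_terms]].copy()
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        gamma0 = cph.params_[list(spec.baseline_terms)].to_numpy()
    except Exception:
        pass
    return gamma0, float(np.log(rate))


# ---------------------------------------------------------------------------
# Fitting


def fit_joint_model(
    dataset: Dataset, spec: JointModelSpec, config: FitConfig | None = None
) -> FitResult:
    """Maximize the joint log likelihood; returns estimates plus Var on the
    unconstrained scale (inverse numerical Hessian). Deterministic given the
    data and config."""
    config = config or FitConfig()
    if int(dataset.survival["event"].sum()) == 0:
        raise ValueError("cannot fit a joint model with zero events")

    data = _FitData(dataset, spec)
    beta0, sigma2_0, Sigma0 = _lmm_stage(dataset, spec, data)
    gamma0, log_h0 = _survival_stage(dataset, spec)
    params0 = ParameterSet(
        gamma_h0=np.full(spec.bh_basis.size, log_h0),
        beta=beta0,
        gamma=gamma0,
        alpha=0.0,
        sigma2=sigma2_0,
        Sigma_b=Sigma0,
    )
    transform = ParameterTransform(spec.bh_basis.size, spec.p_beta, spec.q_gamma, spec.dim_b)
    x0 = transform.pack(params0)

    def nll(theta: np.ndarray) -> float:
        try:
            p = transform.unpack(theta)
            val = joint_log_likelihood(p, dataset, spec, rule=config.n_quad, _data=data)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return 1e10
        if not np.isfinite(val) or val > 1e8:
            return 1e10
        return -val

    with np.errstate(over="ignore", invalid="ignore"):
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iter,
                "ftol": config.ftol,
                "gtol": config.pgtol,
                "maxcor": 25,
            },
        )
    theta_hat = res.x
    params_hat = transform.unpack(theta_hat)
    loglik = -float(res.fun)
    converged = bool(res.success)

    vcov = None
    if config.compute_vcov and converged:
        H = _numerical_hessian(nll, theta_hat)
        vcov = _safe_inverse(H)

    return FitResult(
        params=params_hat,
        spec=spec,
        vcov_unconstrained=vcov,
        transform=transform,
        loglik=loglik,
        converged=converged,
        n_quad=config.n_quad,
        eb_modes=_eb_centers_b_space(data, params_hat),
    )


def _eb_centers_b_space(data: _FitData, params: ParameterSet):
    """Final adaptive centers mapped back to the b scale (modes, scale factors)."""
    T = _whitening_factor(params.Sigma_b)
    if T.shape[1] == 0:
        d = data.dim_b
        return np.zeros((data.n, d)), np.zeros((data.n, d, d))
    mu, Ls = _posterior_centers_u(data, params, T)
    return mu @ T.T, np.einsum("dr,nrs->nds", T, Ls)


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    p = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    """Invert the Hessian, flooring flat/negative curvature directions.

    Directions with (numerically) no curvature — typically Sigma_b boundary
    parameters — would otherwise receive near-infinite sampling variance and
    derail the simulation-based SE scheme; the floor caps their unconstrained-
    scale variance at ~1e4 / max curvature.
    """
    H = 0.5 * (H + H.T)
    eigval, eigvec = np.linalg.eigh(H)
    floor = max(1e-8, 1e-4 * float(np.abs(eigval).max()))
    if np.any(eigval < floor):
        warnings.warn("Hessian not positive definite; eigenvalues floored for vcov")
        eigval = np.clip(eigval, floor, None)
    return eigvec @ np.diag(1.0 / eigval) @ eigvec.T


def empirical_bayes_modes(fit: FitResult, dataset: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject maximizer of the joint integrand over b, with curvature.

    Returns (modes (n, d), inverse-Hessian Cholesky factors (n, d, d)); falls
    back to the prior scale with a warning where the local surface is not
    concave.
    """
    if not fit.converged:
        raise ValueError("empirical Bayes modes require a converged fit")
    data = _FitData(dataset, fit.spec)
    params = fit.params
    d = data.dim_b
    prior_pd = not np.allclose(params.Sigma_b, 0.0, atol=1e-12)
    modes = np.zeros((data.n, d))
    chols = np.zeros((data.n, d, d))
    for i in range(data.n):
        sub = _SubjectSlice(data, i)

        def neg_logpost(b: np.ndarray) -> float:
            val = sub.log_integrand(params, b)
            if prior_pd:
                val += float(
                    -0.5 * b @ np.linalg.solve(params.Sigma_b, b)
                )
            return -val

        res = optimize.minimize(neg_logpost, np.zeros(d), method="BFGS")
        modes[i] = res.x
        Hinv = 0.5 * (res.hess_inv + res.hess_inv.T)
        try:
            chols[i] = np.linalg.cholesky(Hinv)
        except np.linalg.LinAlgError:
            warnings.warn(f"non-concave EB surface for subject {data.ids[i]!r}; using prior scale")
            chols[i] = np.linalg.cholesky(params.Sigma_b + np.eye(d) * 1e-8)
    return modes, chols


class _SubjectSlice:
    """Single-subject view of the integrand (used for EB mode search)."""

    def __init__(self, data: _FitData, i: int):
        self.data, self.i = data, i
        self.rows = data.subj == i

    def log_integrand(self, params: ParameterSet, b: np.ndarray) -> float:
        data, i = self.data, self.i
        b_nodes = np.zeros((data.n, 1, data.dim_b))
        b_nodes[i, 0] = b
        terms = _integrand_terms(data, params, b_nodes)
        return float(terms[i, 0])
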