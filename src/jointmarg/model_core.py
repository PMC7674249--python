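"""Joint-model specification, parameter vector, design construction and hazards.

The longitudinal fixed/random structures are described by small polynomial
terms (a product of covariates times a power of time), parsed from
formula-like strings such as ``"1 + time + trt:time"``. Because every term is
polynomial in time, the slope and cumulative association transforms have exact
closed forms; the numerical approximations in :mod:`jointmarg.numerics` are
kept as an independent cross-check route.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from . import numerics

__all__ = [
    "Term",
    "parse_formula",
    "BaselineHazardBasis",
    "ParameterSet",
    "JointModelSpec",
    "Dataset",
    "StackedDesign",
    "TreatmentContrast",
    "validate_dataset",
    "linear_predictor",
    "association_feature",
    "conditional_hazard",
    "build_stacked_design",
    "treatment_contrast",
    "DatasetValidationError",
    "RankDeficiencyError",
    "TIME_FLOOR",
]

#: Rows at t = 0 are evaluated at this floor so the log baseline hazard stays finite.
TIME_FLOOR = 1e-6

ASSOCIATIONS = ("value", "slope", "cumulative")


class DatasetValidationError(ValueError):
    """A longitudinal/survival table pair violates a dataset invariant."""


class RankDeficiencyError(np.linalg.LinAlgError):
    """A design matrix is rank deficient; a least-squares projection would be unidentified."""


# ---------------------------------------------------------------------------
# Polynomial design terms


@dataclass(frozen=True)
class Term:
    """One design column: ``prod(covariates) * t**power``."""

    covariates: tuple[str, ...]
    power: int

    def value(self, covariate_values: Mapping[str, float], t: float | np.ndarray):
        c = 1.0
        for name in self.covariates:
            c *= float(covariate_values[name])
        return c * np.power(t, self.power) if self.power else c * np.ones_like(np.asarray(t, dtype=float))

    def derivative(self) -> "Term | None":
        """d/dt of the term, or None if it vanishes (constant in t)."""
        if self.power == 0:
            return None
        return Term(self.covariates, self.power - 1)

    def antiderivative(self) -> "Term":
        return Term(self.covariates, self.power + 1)

    def __str__(self) -> str:  # pragma: no cover - display only
        parts = list(self.covariates)
        if self.power == 1:
            parts.append("time")
        elif self.power > 1:
            parts.append(f"time^{self.power}")
        return ":".join(parts) if parts else "1"


_TIME_FACTOR = re.compile(r"^(?:time|t)(?:\^|\*\*)?(\d+)?$")


def parse_formula(formula: str | Sequence[str]) -> tuple[Term, ...]:
    """Parse ``"1 + time + trt:time"``-style formulas into polynomial terms."""
    if isinstance(formula, str):
        pieces = [p.strip() for p in formula.split("+")]
    else:
        pieces = [str(p).strip() for p in formula]
    terms: list[Term] = []
    for piece in pieces:
        if not piece:
            raise ValueError(f"empty term in formula {formula!r}")
        covs: list[str] = []
        power = 0
        for factor in (f.strip() for f in piece.split(":")):
            if factor == "1":
                continue
            m = _TIME_FACTOR.match(factor)
            if m:
                power += int(m.group(1)) if m.group(1) else 1
            else:
                covs.append(factor)
        terms.append(Term(tuple(covs), power))
    return tuple(terms)


# ---------------------------------------------------------------------------
# Baseline hazard basis


@dataclass(frozen=True)
class BaselineHazardBasis:
    """B-spline basis for the log baseline hazard.

    Evaluation returns a row of length ``q = len(interior_knots) + degree + 1``
    for any time within ``boundary``.
    """

    degree: int
    interior_knots: tuple[float, ...]
    boundary: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if lo >= hi:
            raise ValueError("boundary must satisfy t_lo < t_hi")
        knots = np.asarray(self.interior_knots, dtype=float)
        if knots.size and (np.any(np.diff(knots) <= 0) or knots[0] <= lo or knots[-1] >= hi):
            raise ValueError("interior knots must be strictly increasing and inside the boundary")

    @property
    def size(self) -> int:
        return len(self.interior_knots) + self.degree + 1

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate(
            [np.full(self.degree + 1, lo), self.interior_knots, np.full(self.degree + 1, hi)]
        )

    def evaluate(self, times: float | np.ndarray) -> np.ndarray:
        """Basis row(s) at the given time(s); raises outside the boundary."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.boundary
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            bad = t[(t < lo - 1e-12) | (t > hi + 1e-12)]
            raise ValueError(f"time(s) {bad} outside baseline-hazard boundary {self.boundary}")
        t = np.clip(t, lo, hi)
        dm = BSpline.design_matrix(t, self.knot_vector, self.degree, extrapolate=False)
        out = np.asarray(dm.todense(), dtype=float)
        return out[0] if np.isscalar(times) or np.ndim(times) == 0 else out

    @staticmethod
    def from_times(times: np.ndarray, degree: int = 3, n_interior: int = 2) -> "BaselineHazardBasis":
        """Default basis: boundary [0, max T], interior knots at quantiles."""
        times = np.asarray(times, dtype=float)
        hi = float(times.max())
        qs = np.quantile(times, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else np.array([])
        qs = np.unique(np.clip(qs, hi * 1e-6, hi * (1 - 1e-6)))
        return BaselineHazardBasis(degree, tuple(float(q) for q in qs), (0.0, hi))


# ---------------------------------------------------------------------------
# Parameters and model spec


@dataclass(frozen=True)
class ParameterSet:
    """Full joint-model parameter vector (gamma_h0, beta, gamma, alpha, sigma2, Sigma_b)."""

    gamma_h0: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    alpha: float
    sigma2: float
    Sigma_b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma_h0", np.asarray(self.gamma_h0, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "gamma", np.atleast_1d(np.asarray(self.gamma, dtype=float)))
        object.__setattr__(self, "Sigma_b", np.asarray(self.Sigma_b, dtype=float))
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        numerics._check_psd(self.Sigma_b)

    @property
    def dim_b(self) -> int:
        return self.Sigma_b.shape[0]

    def to_dict(self) -> dict:
        return {
            "gamma_h0": self.gamma_h0.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "alpha": float(self.alpha),
            "sigma2": float(self.sigma2),
            "Sigma_b": self.Sigma_b.tolist(),
        }

    @staticmethod
    def from_dict(d: Mapping) -> "ParameterSet":
        return ParameterSet(
            np.asarray(d["gamma_h0"]), np.asarray(d["beta"]), np.asarray(d["gamma"]),
            float(d["alpha"]), float(d["sigma2"]), np.asarray(d["Sigma_b"]),
        )


@dataclass(frozen=True)
class JointModelSpec:
    """Symbolic description of both submodels and their association."""

    fixed_terms: tuple[Term, ...]
    random_terms: tuple[Term, ...]
    baseline_terms: tuple[str, ...]
    association: str
    bh_basis: BaselineHazardBasis
    treatment_name: str

    def __post_init__(self) -> None:
        if self.association not in ASSOCIATIONS:
            raise ValueError(f"unsupported association {self.association!r}; one of {ASSOCIATIONS}")
        in_fixed = any(self.treatment_name in t.covariates for t in self.fixed_terms)
        if self.treatment_name not in self.baseline_terms and not in_fixed:
            raise ValueError(
                f"treatment {self.treatment_name!r} appears in neither submodel"
            )

    @property
    def p_beta(self) -> int:
        return len(self.fixed_terms)

    @property
    def dim_b(self) -> int:
        return len(self.random_terms)

    @property
    def q_gamma(self) -> int:
        return len(self.baseline_terms)

    def to_dict(self) -> dict:
        return {
            "fixed": [str(t) for t in self.fixed_terms],
            "random": [str(t) for t in self.random_terms],
            "baseline": list(self.baseline_terms),
            "association": self.association,
            "bh_basis": {
                "degree": self.bh_basis.degree,
                "interior_knots": list(self.bh_basis.interior_knots),
                "boundary": list(self.bh_basis.boundary),
            },
            "treatment": self.treatment_name,
        }

    @staticmethod
    def from_dict(d: Mapping) -> "JointModelSpec":
        bh = d["bh_basis"]
        return JointModelSpec(
            fixed_terms=parse_formula(d["fixed"]),
            random_terms=parse_formula(d["random"]),
            baseline_terms=tuple(d["baseline"]),
            association=d["association"],
            bh_basis=BaselineHazardBasis(
                int(bh["degree"]), tuple(float(k) for k in bh["interior_knots"]),
                (float(bh["boundary"][0]), float(bh["boundary"][1])),
            ),
            treatment_name=d["treatment"],
        )


# ---------------------------------------------------------------------------
# Dataset


@dataclass(frozen=True)
class Dataset:
    """Validated longitudinal + survival tables.

    ``longitudinal`` has columns ``id, time, y`` plus covariates; ``survival``
    has ``id, time, event`` plus baseline covariates (incl. the treatment
    indicator).
    """

    longitudinal: pd.DataFrame
    survival: pd.DataFrame

    @property
    def N(self) -> int:
        return len(self.longitudinal)

    @property
    def n(self) -> int:
        return len(self.survival)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.survival["id"].to_numpy()

    def subject_covariates(self, subject_id) -> dict[str, float]:
        row = self.survival.loc[self.survival["id"] == subject_id]
        if row.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        rec = row.iloc[0].to_dict()
        rec.pop("time"), rec.pop("event")
        return rec


def validate_dataset(long_table: pd.DataFrame, surv_table: pd.DataFrame) -> Dataset:
    """Validate the two tables and return a :class:`Dataset`.

    Rejects (never silently drops) longitudinal rows observed after the
    subject's survival time, event indicators outside {0, 1}, negative times,
    and longitudinal subjects missing from the survival table.
    """
    for name, tab, cols in (
        ("longitudinal", long_table, ("id", "time", "y")),
        ("survival", surv_table, ("id", "time", "event")),
    ):
        if tab is None or len(tab) == 0:
            raise DatasetValidationError(f"{name} table is empty")
        missing = [c for c in cols if c not in tab.columns]
        if missing:
            raise DatasetValidationError(f"{name} table missing column(s) {missing}")

    surv = surv_table.reset_index(drop=True)
    long = long_table.reset_index(drop=True)

    if surv["id"].duplicated().any():
        dup = surv.loc[surv["id"].duplicated(), "id"].iloc[0]
        raise DatasetValidationError(f"duplicate survival row for subject {dup!r}")

    bad_event = ~surv["event"].isin([0, 1])
    if bad_event.any():
        sub = surv.loc[bad_event].iloc[0]
        raise DatasetValidationError(
            f"event indicator {sub['event']!r} not in {{0, 1}} for subject {sub['id']!r}"
        )

    for name, tab in (("longitudinal", long), ("survival", surv)):
        neg = tab["time"] < 0
        if neg.any():
            sub = tab.loc[neg].iloc[0]
            raise DatasetValidationError(
                f"negative time {sub['time']} in {name} table for subject {sub['id']!r}"
            )

    t_by_id = surv.set_index("id")["time"]
    unknown = ~long["id"].isin(t_by_id.index)
    if unknown.any():
        sub = long.loc[unknown, "id"].iloc[0]
        raise DatasetValidationError(f"longitudinal subject {sub!r} missing from survival table")

    t_obs = long["id"].map(t_by_id)
    late = long["time"] > t_obs + 1e-12
    if late.any():
        sub = long.loc[late].iloc[0]
        raise DatasetValidationError(
            f"longitudinal time {sub['time']} after survival time for subject {sub['id']!r}"
        )

    return Dataset(longitudinal=long, survival=surv)


# ---------------------------------------------------------------------------
# Design evaluation


def _terms_matrix(terms: Iterable[Term], covariates: Mapping[str, float], times: np.ndarray) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    cols = [np.broadcast_to(t.value(covariates, times), times.shape).astype(float) for t in terms]
    return np.column_stack(cols) if cols else np.empty((len(times), 0))


def _transformed_terms_matrix(
    terms: tuple[Term, ...],
    covariates: Mapping[str, float],
    times: np.ndarray,
    association: str,
) -> np.ndarray:
    """Design rows with the association transform applied (exact closed forms)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if association == "value":
        return _terms_matrix(terms, covariates, times)
    if association == "slope":
        cols = []
        for term in terms:
            d = term.derivative()
            if d is None:
                cols.append(np.zeros(len(times)))
            else:
                cols.append(term.power * np.broadcast_to(d.value(covariates, times), times.shape))
        return np.column_stack(cols) if cols else np.empty((len(times), 0))
    if association == "cumulative":
        cols = []
        for term in terms:
            a = term.antiderivative()
            cols.append(np.broadcast_to(a.value(covariates, times), times.shape) / (term.power + 1))
        return np.column_stack(cols) if cols else np.empty((len(times), 0))
    raise ValueError(f"unsupported association {association!r}")


def _numeric_transformed_row(
    terms: tuple[Term, ...],
    covariates: Mapping[str, float],
    t: float,
    association: str,
    eps: float = 1e-3,
) -> np.ndarray:
    """Independent numeric route for the slope/cumulative transforms."""
    x_fun = lambda s: _terms_matrix(terms, covariates, np.array([s]))[0]
    if association == "value":
        return x_fun(t)
    if association == "slope":
        return numerics.central_difference_row(x_fun, t, eps=eps, lower_bound=0.0)
    if association == "cumulative":
        return numerics.cumulative_row(x_fun, t)
    raise ValueError(f"unsupported association {association!r}")


def baseline_covariate_row(spec: JointModelSpec, covariates: Mapping[str, float]) -> np.ndarray:
    return np.array([float(covariates[name]) for name in spec.baseline_terms])


def linear_predictor(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    b: Sequence[float],
    t: float,
) -> float:
    """True longitudinal value eta_i(t) = x_i(t)' beta + z_i(t)' b_i."""
    b = np.asarray(b, dtype=float)
    if b.shape[-1] != spec.dim_b:
        raise ValueError(f"b has length {b.shape[-1]}, expected {spec.dim_b}")
    if len(params.beta) != spec.p_beta:
        raise ValueError(f"beta has length {len(params.beta)}, expected {spec.p_beta}")
    x = _terms_matrix(spec.fixed_terms, covariates, np.array([t]))[0]
    z = _terms_matrix(spec.random_terms, covariates, np.array([t]))[0]
    return float(x @ params.beta + z @ b)


def association_feature(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    b: Sequence[float],
    t: float,
    method: str = "exact",
) -> float:
    """The longitudinal feature entering the hazard (before multiplying by alpha).

    ``value`` returns eta_i(t); ``slope`` its time derivative; ``cumulative``
    its integral over [0, t]. ``method="numeric"`` routes through the
    finite-difference / Gauss-Kronrod approximations instead of the exact
    polynomial closed forms.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    b = np.asarray(b, dtype=float)
    if method == "exact":
        x = _transformed_terms_matrix(spec.fixed_terms, covariates, np.array([t]), spec.association)[0]
        z = _transformed_terms_matrix(spec.random_terms, covariates, np.array([t]), spec.association)[0]
    elif method == "numeric":
        x = _numeric_transformed_row(spec.fixed_terms, covariates, t, spec.association)
        z = _numeric_transformed_row(spec.random_terms, covariates, t, spec.association)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(x @ params.beta + z @ b)


def log_conditional_hazard(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    b: Sequence[float],
    t: float,
) -> float:
    if t <= 0:
        raise ValueError("t must be > 0")
    wh0 = spec.bh_basis.evaluate(float(t))
    w = baseline_covariate_row(spec, covariates)
    feat = association_feature(spec, params, covariates, b, t)
    return float(wh0 @ params.gamma_h0 + w @ params.gamma + params.alpha * feat)


def conditional_hazard(
    spec: JointModelSpec,
    params: ParameterSet,
    covariates: Mapping[str, float],
    b: Sequence[float],
    t: float,
) -> float:
    """Conditional hazard h_i(t | b) = h0(t) exp{w' gamma + alpha f(H_i(t))}."""
    return float(np.exp(log_conditional_hazard(spec, params, covariates, b, t)))


def hazard_design(
    spec: JointModelSpec, covariates: Mapping[str, float], times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pieces of the log hazard at many times for one subject.

    Returns ``(Wh0, w, Xstar, Zstar)`` with ``Wh0`` (m, q_h0), ``w`` (q_gamma,),
    ``Xstar``/``Zstar`` the association-transformed fixed/random designs, so
    ``log h(t|b) = Wh0 @ gamma_h0 + w @ gamma + alpha (Xstar @ beta + Zstar @ b)``.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    wh0 = spec.bh_basis.evaluate(times)
    w = baseline_covariate_row(spec, covariates)
    xstar = _transformed_terms_matrix(spec.fixed_terms, covariates, times, spec.association)
    zstar = _transformed_terms_matrix(spec.random_terms, covariates, times, spec.association)
    return wh0, w, xstar, zstar


# ---------------------------------------------------------------------------
# Stacked design


@dataclass(frozen=True)
class StackedDesign:
    """The (N + n) x (q_h0 + dim gamma + 1) stacked matrix [W_h0 | W | X beta].

    ``q_h0`` records the leading block width so projections can split the
    coefficient vector back into (gamma_h0, gamma, alpha) blocks.
    """

    matrix: np.ndarray
    row_index: tuple[tuple[object, float, str], ...]
    q_h0: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def stacked_row_times(dataset: Dataset, include_censored: bool = True):
    """Ordered (subject_id, time, origin) triples: longitudinal rows then the
    subject's observed-time row, subjects in survival-table order."""
    rows: list[tuple[object, float, str]] = []
    long_by_id = {sid: grp for sid, grp in dataset.longitudinal.groupby("id", sort=False)}
    for rec in dataset.survival.itertuples(index=False):
        sid = rec.id
        grp = long_by_id.get(sid)
        if grp is not None:
            rows.extend((sid, float(t), "longitudinal") for t in grp["time"])
        if include_censored or rec.event == 1:
            rows.append((sid, float(rec.time), "event"))
    return rows


def build_stacked_design(
    spec: JointModelSpec,
    params: ParameterSet,
    dataset: Dataset,
    include_censored: bool = True,
) -> StackedDesign:
    """Stack [W_h0 | W | X*beta] over all longitudinal and observed times.

    The last column carries the association-transformed fixed part of the
    longitudinal model times beta. Observed-time rows are included for every
    subject by default (censored subjects contribute their censoring times);
    ``include_censored=False`` restricts to event times.
    """
    rows = stacked_row_times(dataset, include_censored=include_censored)
    cov_by_id = {
        rec["id"]: {k: v for k, v in rec.items() if k not in ("time", "event")}
        for rec in dataset.survival.to_dict("records")
    }
    mat = np.empty((len(rows), spec.bh_basis.size + spec.q_gamma + 1))
    for k, (sid, t, _origin) in enumerate(rows):
        te = max(float(t), TIME_FLOOR)
        cov = cov_by_id[sid]
        wh0 = spec.bh_basis.evaluate(te)
        w = baseline_covariate_row(spec, cov)
        xstar = _transformed_terms_matrix(spec.fixed_terms, cov, np.array([te]), spec.association)[0]
        mat[k] = np.concatenate([wh0, w, [xstar @ params.beta]])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise RankDeficiencyError(
            f"stacked design is rank deficient (shape {mat.shape}); "
            "the marginal projection would be unidentified"
        )
    return StackedDesign(matrix=mat, row_index=tuple(rows), q_h0=spec.bh_basis.size)


# ---------------------------------------------------------------------------
# Treatment contrast


@dataclass(frozen=True)
class TreatmentContrast:
    """Treatment-vs-control design difference, other covariates at reference values."""

    W_bar: np.ndarray
    X_bar: Callable[[float], np.ndarray]


def reference_covariates(dataset: Dataset, spec: JointModelSpec) -> dict[str, float]:
    """Default reference values: mode for binary covariates, mean otherwise."""
    refs: dict[str, float] = {}
    for col in dataset.survival.columns:
        if col in ("id", "time", "event", spec.treatment_name):
            continue
        vals = dataset.survival[col].to_numpy(dtype=float)
        uniq = np.unique(vals)
        refs[col] = float(pd.Series(vals).mode().iloc[0]) if len(uniq) <= 2 else float(vals.mean())
    return refs


def treatment_contrast(
    spec: JointModelSpec, reference: Mapping[str, float] | None = None
) -> TreatmentContrast:
    """W_bar = W(D=1) - W(D=0) and X_bar(t) = X*(D=1, t) - X*(D=0, t).

    ``X_bar`` carries the association transform of the spec, so the overall
    effect exponent is ``W_bar @ gamma + alpha * X_bar(t) @ beta``.
    """
    ref = dict(reference or {})
    trt = spec.treatment_name
    cov1 = {**ref, trt: 1.0}
    cov0 = {**ref, trt: 0.0}
    w_bar = baseline_covariate_row(spec, cov1) - baseline_covariate_row(spec, cov0)

    def x_bar(t: float) -> np.ndarray:
        ts = np.array([float(t)])
        return (
            _transformed_terms_matrix(spec.fixed_terms, cov1, ts, spec.association)[0]
            - _transformed_terms_matrix(spec.fixed_terms, cov0, ts, spec.association)[0]
        )

    return TreatmentContrast(W_bar=w_bar, X_bar=x_bar)
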