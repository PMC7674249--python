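import numpy as np
import pytest

from jointmarg.marginalize import (
    MarginalizationConfig,
    marginal_coefs,
    marginal_log_hazard,
    marginal_log_hazard_oracle,
    conditional_survival,
    project_marginal,
    _log_hazard_draws,
    _mc_marginal_log_hazard_rows,
)
from jointmarg.model_core import (
    ParameterSet,
    StackedDesign,
    build_stacked_design,
    conditional_hazard,
    log_conditional_hazard,
)
from jointmarg.numerics import subject_rng

from conftest import make_spec, truth_fit


def scen2_params(scen2, **overrides):
    p = scen2.params
    kw = dict(
        gamma_h0=p.gamma_h0, beta=p.beta, gamma=p.gamma,
        alpha=p.alpha, sigma2=p.sigma2, Sigma_b=p.Sigma_b,
    )
    kw.update(overrides)
    return ParameterSet(**kw)


class TestConditionalSurvival:
    def test_time_zero_is_one(self, scen2):
        assert conditional_survival(scen2.spec, scen2.params, {"trt": 1.0}, [0, 0], 0.0) == 1.0

    def test_constant_hazard_closed_form(self):
        spec = make_spec(boundary=(0.0, 20.0), interior=(7.0, 13.0))
        c = -0.8
        p = ParameterSet(
            gamma_h0=np.full(spec.bh_basis.size, c),
            beta=np.zeros(3), gamma=np.array([0.0]), alpha=0.0,
            sigma2=0.1, Sigma_b=np.zeros((2, 2)),
        )
        for t in (0.5, 3.0, 11.0):
            got = conditional_survival(spec, p, {"trt": 0.0}, [0, 0], t)
            assert got == pytest.approx(np.exp(-np.exp(c) * t), rel=1e-12)

    def test_matches_brute_force_grid_oracle(self, scen2):
        # brute-force cumulative hazard on a 10,001-point grid (Simpson);
        # smooth (knot-free) baseline so single-interval GK15 is near exact
        from scipy.integrate import simpson

        spec = make_spec(interior=())
        p = ParameterSet(
            gamma_h0=np.array([-1.5, -1.2, -1.0, -1.3]),
            beta=scen2.params.beta, gamma=scen2.params.gamma, alpha=scen2.params.alpha,
            sigma2=scen2.params.sigma2, Sigma_b=scen2.params.Sigma_b,
        )
        t = 8.0
        grid = np.linspace(1e-9, t, 10_001)
        h = np.array(
            [conditional_hazard(spec, p, {"trt": 1.0}, [0.0, 0.0], u) for u in grid]
        )
        oracle = np.exp(-simpson(h, x=grid))
        got = conditional_survival(spec, p, {"trt": 1.0}, [0.0, 0.0], t)
        assert got == pytest.approx(oracle, rel=1e-8)

    def test_nonincreasing_in_t(self, scen2):
        vals = [
            conditional_survival(scen2.spec, scen2.params, {"trt": 1.0}, [0.1, 0.0], t)
            for t in np.linspace(0, 14, 15)
        ]
        assert np.all(np.diff(vals) <= 0)

    def test_negative_t_rejected(self, scen2):
        with pytest.raises(ValueError):
            conditional_survival(scen2.spec, scen2.params, {"trt": 1.0}, [0, 0], -1.0)


class TestMarginalLogHazard:
    def test_zero_variance_equals_conditional(self, scen2):
        p = scen2_params(scen2, Sigma_b=np.zeros((2, 2)))
        cfg = MarginalizationConfig(G=20, K=20, seed=1)
        got = marginal_log_hazard(scen2.spec, p, {"trt": 1.0}, 5.0, cfg)
        expected = log_conditional_hazard(scen2.spec, p, {"trt": 1.0}, [0, 0], 5.0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_alpha_zero_equals_conditional(self, scen2):
        p = scen2_params(scen2, alpha=0.0)
        cfg = MarginalizationConfig(G=50, K=50, seed=2)
        got = marginal_log_hazard(scen2.spec, p, {"trt": 0.0}, 5.0, cfg)
        expected = log_conditional_hazard(scen2.spec, p, {"trt": 0.0}, [0, 0], 5.0)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_1d_random_intercept_matches_gh_oracle(self):
        spec = make_spec(fixed="1 + time + trt:time", random="1")
        p = ParameterSet(
            gamma_h0=np.full(spec.bh_basis.size, -1.0),
            beta=np.array([1.08, -0.08, 0.10]),
            gamma=np.array([1.48]), alpha=-0.5, sigma2=0.1,
            Sigma_b=np.array([[0.3]]),
        )
        t = 6.0
        oracle = marginal_log_hazard_oracle(spec, p, {"trt": 1.0}, t, gh_order=60)
        cfg = lambda s: MarginalizationConfig(G=5000, K=5000, seed=s)
        vals = [marginal_log_hazard(spec, p, {"trt": 1.0}, t, cfg(s)) for s in range(10)]
        assert abs(np.mean(vals) - oracle) <= 3 * np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(vals[0] - oracle) <= 4 * np.std(vals, ddof=1)

    def test_bracketing_with_common_draws(self, scen2):
        # with shared draws the marginal hazard is a weighted mean of conditionals
        spec, p = scen2.spec, scen2.params
        t = np.array([4.0])
        cfg = MarginalizationConfig(G=200, K=200, seed=3, draw_sharing="common")
        rng = subject_rng(cfg.seed, 0)
        from jointmarg.numerics import sample_mvnormal

        b = sample_mvnormal(np.zeros(2), p.Sigma_b, cfg.G, subject_rng(cfg.seed, 0))
        rng = subject_rng(cfg.seed, 0)
        val = _mc_marginal_log_hazard_rows(spec, p, {"trt": 1.0}, t, cfg, rng, observed_time=4.0)[0]
        logh = _log_hazard_draws(spec, p, {"trt": 1.0}, t, b)[0]
        assert logh.min() - 1e-12 <= val <= logh.max() + 1e-12

    def test_mc_error_scales_as_inverse_sqrt_g(self, scen2):
        spec, p = scen2.spec, scen2.params
        t = 6.0
        sds = []
        gs = [500, 2000, 8000]
        for G in gs:
            vals = [
                marginal_log_hazard(
                    spec, p, {"trt": 1.0}, t, MarginalizationConfig(G=G, K=G, seed=s)
                )
                for s in range(20)
            ]
            sds.append(np.std(vals, ddof=1))
        slope = np.polyfit(np.log(gs), np.log(sds), 1)[0]
        assert -0.6 < slope < -0.4

    def test_underflow_raises(self, scen2):
        p = scen2_params(scen2, gamma_h0=scen2.params.gamma_h0 + 800.0)  # overflowing hazard
        with pytest.raises(FloatingPointError):
            marginal_log_hazard(scen2.spec, p, {"trt": 1.0}, 13.0, MarginalizationConfig(G=10, K=10, seed=0))


class TestOracle:
    def test_zero_variance(self, scen2):
        p = scen2_params(scen2, Sigma_b=np.zeros((2, 2)))
        got = marginal_log_hazard_oracle(scen2.spec, p, {"trt": 0.0}, 3.0)
        assert got == pytest.approx(
            log_conditional_hazard(scen2.spec, p, {"trt": 0.0}, [0, 0], 3.0), abs=1e-12
        )

    def test_gh_order_convergence(self, scen2):
        a = marginal_log_hazard_oracle(scen2.spec, scen2.params, {"trt": 1.0}, 6.0, gh_order=40)
        b = marginal_log_hazard_oracle(scen2.spec, scen2.params, {"trt": 1.0}, 6.0, gh_order=60)
        assert abs(a - b) < 1e-8

    def test_normal_kernel_flip_invariance(self):
        # b -> -b symmetry of N(0, Sigma): jointly flipping the sign of alpha
        # and of all mean effects leaves the marginal log hazard unchanged
        spec = make_spec(fixed="1 + time + trt:time", random="1", baseline=("trt",))
        base = dict(
            gamma_h0=np.zeros(spec.bh_basis.size), sigma2=0.1, Sigma_b=np.array([[0.4]])
        )
        for t in (0.5, 2.0, 6.0):
            p_pos = ParameterSet(beta=np.array([0.5, 0.1, 0.2]), gamma=np.array([0.3]), alpha=0.8, **base)
            p_neg = ParameterSet(beta=np.array([-0.5, -0.1, -0.2]), gamma=np.array([0.3]), alpha=-0.8, **base)
            m_pos = marginal_log_hazard_oracle(spec, p_pos, {"trt": 1.0}, t, gh_order=60)
            m_neg = marginal_log_hazard_oracle(spec, p_neg, {"trt": 1.0}, t, gh_order=60)
            assert m_pos == pytest.approx(m_neg, abs=1e-10)

    def test_dim3_unsupported(self):
        spec = make_spec(random="1 + time + time^2")
        p = ParameterSet(
            gamma_h0=np.zeros(spec.bh_basis.size),
            beta=np.array([1.0, 0.0, 0.0]), gamma=np.array([0.0]),
            alpha=0.1, sigma2=0.1, Sigma_b=np.eye(3) * 0.1,
        )
        with pytest.raises(ValueError, match="<= 2"):
            marginal_log_hazard_oracle(spec, p, {"trt": 1.0}, 1.0)


class TestProjectMarginal:
    @staticmethod
    def _random_block_design(seed=0, rows=60, q_h0=4):
        rng = np.random.default_rng(seed)
        X = np.column_stack(
            [rng.uniform(0, 1, (rows, q_h0)), rng.integers(0, 2, rows), rng.normal(0, 1, rows)]
        )
        return StackedDesign(matrix=X, row_index=tuple((i, 0.0, "event") for i in range(rows)), q_h0=q_h0)

    def test_projection_identity(self):
        sd = self._random_block_design()
        theta0 = np.array([0.5, -0.2, 0.1, 0.9, 1.48, -0.5])
        got = project_marginal(sd, sd.matrix @ theta0)
        np.testing.assert_allclose(got.theta, theta0, rtol=1e-10)
        assert got.alpha_M == pytest.approx(-0.5)
        assert got.gamma_M[0] == pytest.approx(1.48)

    def test_orthogonal_residual_ignored(self):
        sd = self._random_block_design(seed=1)
        theta0 = np.array([0.5, -0.2, 0.1, 0.9, 1.48, -0.5])
        rng = np.random.default_rng(2)
        resid = rng.normal(0, 1, sd.shape[0])
        # project the noise off the column space
        Q, _ = np.linalg.qr(sd.matrix)
        resid -= Q @ (Q.T @ resid)
        got = project_marginal(sd, sd.matrix @ theta0 + resid)
        np.testing.assert_allclose(got.theta, theta0, rtol=1e-8, atol=1e-10)

    def test_rank_deficiency_error(self):
        sd = self._random_block_design(seed=3)
        X = sd.matrix.copy()
        X[:, -1] = X[:, 0]  # duplicate column
        bad = StackedDesign(matrix=X, row_index=sd.row_index, q_h0=4)
        with pytest.raises(np.linalg.LinAlgError):
            project_marginal(bad, np.zeros(X.shape[0]))

    def test_length_mismatch(self):
        sd = self._random_block_design()
        with pytest.raises(ValueError):
            project_marginal(sd, np.zeros(3))


class TestMarginalCoefs:
    def test_zero_variance_recovers_ss_exactly(self, scen2, scen2_data):
        p = scen2_params(scen2, Sigma_b=np.zeros((2, 2)))
        fit = truth_fit(scen2.spec, p)
        m = marginal_coefs(fit, scen2_data, MarginalizationConfig(G=50, K=50, seed=1))
        np.testing.assert_allclose(m.gamma_h0_M, p.gamma_h0, atol=1e-8)
        np.testing.assert_allclose(m.gamma_M, p.gamma, atol=1e-8)
        assert m.alpha_M == pytest.approx(p.alpha, abs=1e-8)

    def test_alpha_zero_recovers_ss(self, scen2, scen2_data):
        p = scen2_params(scen2, alpha=0.0)
        fit = truth_fit(scen2.spec, p)
        m = marginal_coefs(fit, scen2_data, MarginalizationConfig(G=100, K=100, seed=1))
        assert m.alpha_M == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(m.gamma_M, p.gamma, atol=1e-6)

    def test_end_to_end_determinism(self, scen2, scen2_data):
        fit = truth_fit(scen2.spec, scen2.params)
        cfg = MarginalizationConfig(G=200, K=200, seed=9)
        a = marginal_coefs(fit, scen2_data, cfg)
        b = marginal_coefs(fit, scen2_data, cfg)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_mc_close_to_oracle_path(self, scen2, scen2_data):
        fit = truth_fit(scen2.spec, scen2.params)
        m_mc = marginal_coefs(
            fit, scen2_data, MarginalizationConfig(G=4000, K=4000, seed=0, draw_sharing="common")
        )
        m_or = marginal_coefs(
            fit, scen2_data, MarginalizationConfig(seed=0), method="oracle", gh_order=40
        )
        assert m_mc.alpha_M == pytest.approx(m_or.alpha_M, abs=0.05)

    def test_cumulative_design_column_expansion(self, scen2):
        # quadratic-trend model under the cumulative parameterization:
        # the X*beta column is b-free and equals
        # beta0 t + beta1 (trt t) + beta2 t^2/2 + beta3 t^3/3 + beta4 trt t^2/2 + beta5 trt t^3/3
        import pandas as pd
        from jointmarg.model_core import validate_dataset

        spec = make_spec(
            fixed="1 + trt + time + time^2 + trt:time + trt:time^2",
            random="1 + time",
            association="cumulative",
        )
        beta = np.array([0.7, 0.4, -0.1, 0.02, 0.15, -0.01])
        p = ParameterSet(
            gamma_h0=np.zeros(spec.bh_basis.size), beta=beta, gamma=np.array([1.0]),
            alpha=-0.2, sigma2=0.1, Sigma_b=np.eye(2) * 0.01,
        )
        long = pd.DataFrame(
            {
                "id": [1, 1, 1, 2, 2, 2, 3, 3, 4, 4],
                "time": [0.0, 2.0, 4.5, 0.0, 3.0, 6.5, 1.0, 8.0, 2.5, 9.5],
                "y": [1.0] * 10,
                "trt": [0, 0, 0, 1, 1, 1, 0, 0, 1, 1],
            }
        )
        surv = pd.DataFrame(
            {
                "id": [1, 2, 3, 4],
                "time": [5.0, 7.0, 11.0, 12.5],
                "event": [1, 1, 0, 1],
                "trt": [0.0, 1.0, 0.0, 1.0],
            }
        )
        ds = validate_dataset(long, surv)
        sd = build_stacked_design(spec, p, ds)
        trt_by_id = dict(zip(surv["id"], surv["trt"]))
        for k, (sid, t, _) in enumerate(sd.row_index):
            trt = trt_by_id[sid]
            te = max(t, 1e-6)
            expected = (
                beta[0] * te + beta[1] * trt * te + beta[2] * te**2 / 2 + beta[3] * te**3 / 3
                + beta[4] * trt * te**2 / 2 + beta[5] * trt * te**3 / 3
            )
            assert sd.matrix[k, -1] == pytest.approx(expected, rel=1e-12, abs=1e-12)
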