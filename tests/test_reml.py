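import numpy as np
import pytest
from scipy import sparse
from scipy.optimize import minimize, minimize_scalar

from microsens.genomics import GRM
from microsens.mme import RandomTerm, ResidualClass
from microsens.reml import MixedModel, compute_leverages, weighted_gamma_glm


def one_way_model(y, groups, n_groups):
    n = len(y)
    Z = sparse.csr_matrix((np.ones(n), (np.arange(n), groups)),
                          shape=(n, n_groups))
    return MixedModel(np.asarray(y, float), np.ones((n, 1)),
                      [RandomTerm("group", Z)],
                      [ResidualClass("e", np.arange(n))])


class TestREMLOracles:
    def test_balanced_anova_closed_form(self):
        # groups A = {0, 2}, B = {4, 6}: MSB = 16, MSW = 2, r = 2
        # REML equals the ANOVA estimators: sigma2_group = 7, sigma2_e = 2
        model = one_way_model([0, 2, 4, 6], [0, 0, 1, 1], 2)
        res = model.fit(tol=1e-10)
        assert res.vc["group:var"] == pytest.approx(7.0, abs=1e-6)
        assert res.vc["resid:e"] == pytest.approx(2.0, abs=1e-6)

    def test_two_residual_classes_profile_oracle(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(0, 1, 40), rng.normal(0, 3, 40)])
        classes = [ResidualClass("a", np.arange(40)),
                   ResidualClass("b", np.arange(40, 80))]
        model = MixedModel(y, np.ones((80, 1)), [], classes)
        res = model.fit(tol=1e-12)

        # independent oracle: numerically maximize the restricted likelihood
        # over the two class variances
        def negll(logv):
            return -model.reml_loglik(np.exp(logv))
        opt = minimize(negll, np.log(res.vc.estimates * 1.7),
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14})
        assert np.allclose(res.vc.estimates, np.exp(opt.x), atol=1e-6)

    def test_boundary_variance_pinned_at_zero(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.0, 1.0, 60)            # no group signal at all
        groups = np.arange(60) % 6
        model = one_way_model(y, groups, 6)
        res = model.fit()
        assert res.vc["group:var"] < 1e-4

    def test_derivative_free_agreement_100_obs(self):
        rng = np.random.default_rng(4)
        n_groups, reps = 20, 5
        groups = np.repeat(np.arange(n_groups), reps)
        u = rng.normal(0, np.sqrt(2.0), n_groups)
        y = 1.0 + u[groups] + rng.normal(0, 1.0, 100)
        model = one_way_model(y, groups, n_groups)
        res = model.fit(tol=1e-10)

        def negll(theta):
            theta = np.abs(theta)
            try:
                return -model.reml_loglik(theta)
            except np.linalg.LinAlgError:
                return np.inf
        opt = minimize(negll, res.vc.estimates * 1.5, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 2000})
        assert np.allclose(res.vc.estimates, np.abs(opt.x), atol=1e-4)


class TestLeverages:
    def test_intercept_only_ols(self):
        model = MixedModel(np.array([1.0, 2.0, 3.0, 4.0]), np.ones((4, 1)),
                           [], [ResidualClass("e", np.arange(4))])
        res = model.fit()
        assert np.allclose(compute_leverages(res), 0.25)

    def test_fixed_rank_equals_leverage_sum(self, rng):
        n, p = 30, 4
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + rng.standard_normal(n)
        model = MixedModel(y, X, [], [ResidualClass("e", np.arange(n))])
        res = model.fit()
        assert compute_leverages(res).sum() == pytest.approx(p, abs=1e-8)

    def test_mixed_model_matches_dense_inverse(self, rng):
        # n <= 50 oracle: assemble H = [X Z] C^{-1} [X Z]' R^{-1} explicitly
        n, q = 48, 8
        groups = rng.integers(0, q, n)
        Z = sparse.csr_matrix((np.ones(n), (np.arange(n), groups)),
                              shape=(n, q))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n) + rng.normal(0, 1, q)[groups]
        model = MixedModel(y, X, [RandomTerm("g", Z)],
                           [ResidualClass("e", np.arange(n))])
        res = model.fit()
        sysm = res.system
        TX = sysm.TX.toarray()
        C = TX.T @ np.diag(sysm.rinv) @ TX
        a, b = sysm.col_offsets["g"]
        C[np.arange(a, b), np.arange(a, b)] += 1.0 / res.vc["g:var"]
        H = TX @ np.linalg.inv(C) @ TX.T @ np.diag(sysm.rinv)
        assert np.allclose(res.leverages(), np.diag(H), atol=1e-8)
        lev = res.leverages()
        assert (lev >= 0).all() and (lev < 1).all()


class TestInvariances:
    def test_reference_level_reparameterization(self, rng):
        n = 60
        groups = np.arange(n) % 6
        trt = (np.arange(n) // 30).astype(float)
        y = 2.0 + trt + rng.normal(0, 1, n) + rng.normal(0, 1, 6)[groups]
        Z = sparse.csr_matrix((np.ones(n), (np.arange(n), groups)),
                              shape=(n, 6))
        X1 = np.column_stack([np.ones(n), trt])         # reference = level 0
        X2 = np.column_stack([np.ones(n), 1.0 - trt])   # reference = level 1
        vcs = []
        for X in (X1, X2):
            model = MixedModel(y, X, [RandomTerm("g", Z)],
                               [ResidualClass("e", np.arange(n))])
            vcs.append(model.fit(tol=1e-10).vc.estimates)
        assert np.allclose(vcs[0], vcs[1], atol=1e-6)

    def test_grm_blups_sum_to_zero_with_centered_grm(self, tiny_sim):
        # rows of an in-sample GRM sum to 0, so with an intercept the
        # genomic BLUPs are a contrast summing to ~0
        cfg, pheno, geno, grm, truth = tiny_sim
        from microsens.models import LMMHet
        res = LMMHet(pheno, grm).fit()
        scale = np.abs(res.g_hat).sum() + 1e-12
        assert abs(res.g_hat.sum()) / scale < 1e-4


class TestGammaGLM:
    def test_intercept_is_log_weighted_mean(self):
        # direct likelihood oracle: intercept-only gamma/log MLE = ln(mean)
        fit = weighted_gamma_glm(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)))
        assert fit.coef[0] == pytest.approx(np.log(2.0), abs=1e-8)

        def neg_loglik(beta):
            mu = np.exp(beta)
            return np.sum(np.log(mu) + np.array([1.0, 2.0, 3.0]) / mu)
        opt = minimize_scalar(neg_loglik, bounds=(-3, 3), method="bounded")
        assert fit.coef[0] == pytest.approx(opt.x, abs=1e-5)

    def test_constant_response_saturated(self):
        fit = weighted_gamma_glm(np.full(5, 3.7), np.ones((5, 1)))
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.fitted, 3.7)

    def test_weight_scale_invariance(self, rng):
        y = rng.gamma(2.0, 1.0, 40) + 0.1
        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        w = rng.uniform(0.2, 1.0, 40)
        f1 = weighted_gamma_glm(y, X, weights=w)
        f2 = weighted_gamma_glm(y, X, weights=2 * w)
        assert np.allclose(f1.coef, f2.coef, atol=1e-8)

    def test_nonpositive_response_rejected(self):
        with pytest.raises(ValueError):
            weighted_gamma_glm(np.array([1.0, 0.0]), np.ones((2, 1)))

    def test_working_response_linearization(self, rng):
        y = rng.gamma(2.0, 1.0, 30) + 0.1
        X = np.ones((30, 1))
        fit = weighted_gamma_glm(y, X)
        assert np.allclose(fit.working_response,
                           fit.eta + (y - fit.fitted) / fit.fitted)


class TestFixedParams:
    def test_fixed_residual_scale_is_honored(self, rng):
        y = rng.normal(0, 2.0, 50)
        model = MixedModel(y, np.ones((50, 1)), [],
                           [ResidualClass("e", np.arange(50))],
                           fixed_params={"resid:e": 1.0})
        res = model.fit()
        assert res.vc["resid:e"] == 1.0
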