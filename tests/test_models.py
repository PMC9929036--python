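import numpy as np
import pandas as pd
import pytest

from microsens.models import (DHGLM, LMMHet, SpatialCorrection,
                              assemble_design, compute_dispersion_response,
                              fit_spatial_stage, log_transform_refit)
from microsens.mme import RandomTerm, ResidualClass
from microsens.reml import MixedModel
from microsens.simulate import SimConfig, simulate_dataset


class TestAssembleDesign:
    def test_two_trials_two_fixed_columns(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        d = assemble_design(pheno, grm)
        n_trials = pheno["trial"].nunique()
        assert d.X.shape[1] == n_trials          # intercept + (n_trials - 1)
        assert d.fixed_names[0] == "intercept"

    def test_line_incidence_one_per_row(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        d = assemble_design(pheno, grm)
        assert (np.diff(d.Z_line.indptr) == 1).all()
        assert (d.Z_line.sum(axis=1) == 1).all()

    def test_missing_genotype_rejected(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        bad = pheno.copy()
        bad.loc[bad.index[0], "line"] = "NOT_A_LINE"
        with pytest.raises(ValueError, match="without genotypes"):
            assemble_design(bad, grm)


@pytest.fixture(scope="module")
def spatial_sim():
    cfg = SimConfig(n_lines=80, n_snps=600, n_envs=2, blocks_per_trial=4,
                    var_s=0.05, var_gd=0.0, rho=0.0, seed=31)
    return cfg, *simulate_dataset(cfg)


class TestSpatialStage:

    def test_recovers_spatial_signal(self, spatial_sim):
        cfg, pheno, geno, grm, truth = spatial_sim
        from microsens.simulate import neighborhood_incidence
        corrected = fit_spatial_stage(pheno, grm)
        z = neighborhood_incidence(pheno)
        true_sum = z @ truth.s
        est_sum = corrected.spatial_contribution
        assert np.corrcoef(true_sum, est_sum)[0, 1] > 0.5

    def test_no_signal_leaves_phenotypes_nearly_unchanged(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim        # var_s = 0
        corrected = fit_spatial_stage(pheno, grm)
        assert np.corrcoef(corrected.y_c, pheno["yield"])[0, 1] > 0.99
        assert list(corrected.pheno.index) == list(range(len(pheno)))

    def test_duplicate_coordinates_rejected(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        bad = pheno.copy()
        bad.loc[bad.index[1], ["x", "y"]] = bad.loc[bad.index[0], ["x", "y"]].values
        with pytest.raises(ValueError, match="duplicate"):
            SpatialCorrection(bad, grm)

    def test_missing_coordinates_rejected(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        bad = pheno.copy()
        bad.loc[bad.index[0], "x"] = np.nan
        with pytest.raises(ValueError, match="[Mm]issing"):
            SpatialCorrection(bad, grm)


class TestLMMHet:
    def test_env_variance_ordering(self):
        # one environment simulated with 4x residual variance should get
        # the largest estimate in most replicates
        wins = 0
        for seed in range(5):
            cfg = SimConfig(n_lines=60, n_snps=400, n_envs=3,
                            blocks_per_trial=3, var_s=0.0, var_gd=0.0,
                            rho=0.0, seed=100 + seed,
                            trial_disp_effects=(np.log(4.0), 0.0, 0.0))
            pheno, geno, grm, truth = simulate_dataset(cfg)
            pheno["y_c"] = pheno["yield"]
            res = LMMHet(pheno, grm).fit()
            est = res.sigma2_e_by_env()
            inflated = "2013_Skive"      # first trial carries the ln(4) offset
            if est[inflated] == max(est.values()):
                wins += 1
        assert wins >= 4

    def test_homogeneous_truth_bounded_spread(self, tiny_lmm):
        est = tiny_lmm.sigma2_e_by_env()
        vals = list(est.values())
        assert max(vals) / min(vals) < 1.6

    def test_single_env_equals_homoscedastic_fit(self):
        cfg = SimConfig(n_lines=50, n_snps=300, n_envs=1, blocks_per_trial=3,
                        var_s=0.0, var_gd=0.0, rho=0.0, seed=55)
        pheno, geno, grm, truth = simulate_dataset(cfg)
        pheno["y_c"] = pheno["yield"]
        het = LMMHet(pheno, grm).fit()
        d = het.model.design
        y = np.asarray(pheno["y_c"], float)
        plain = MixedModel(
            y, d.X,
            [RandomTerm("g", d.Z_line, kind="grm", grm=grm),
             RandomTerm("l", d.Z_line, kind="iid"),
             RandomTerm("f", d.Z_f, kind="iid")],
            [ResidualClass("e", np.arange(len(y)))],
        ).fit(start=np.array([0.2, 0.2, 0.3, 0.3]) * np.var(y))
        assert np.allclose(het.vc.estimates, plain.vc.estimates, atol=1e-6)

    def test_env_with_single_observation_rejected(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        bad = pd.concat([pheno, pheno.iloc[[0]].assign(env="lonely",
                                                       trial="lonely_T1")],
                        ignore_index=True)
        with pytest.raises(ValueError, match="< 2 observations"):
            LMMHet(bad, grm)


class TestDispersionResponse:
    def test_arithmetic(self):
        assert compute_dispersion_response(0.3, 0.1) == pytest.approx(0.1)
        assert compute_dispersion_response(0.0, 0.5) == 0.0
        assert compute_dispersion_response(1.5, 0.0) == pytest.approx(2.25)

    def test_leverage_domain(self):
        with pytest.raises(ValueError):
            compute_dispersion_response(1.0, 1.0)
        with pytest.raises(ValueError):
            compute_dispersion_response(1.0, -0.1)


class TestDHGLM:
    def test_convergence_contract(self, tiny_dhglm):
        res = tiny_dhglm
        assert res.converged
        assert res.outer_trace[-1]["rel_change"] < 1e-5 or res.n_outer >= 12
        lev = res.leverage
        assert (lev >= 0).all() and (lev < 1).all()

    def test_scales_fixed_at_one(self, tiny_dhglm):
        assert tiny_dhglm.sigma2_e_scale == 1.0
        assert tiny_dhglm.sigma2_ev_scale == 1.0

    def test_mean_dispersion_response_tracks_residual_variance(self, tiny_dhglm,
                                                               tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        # converged mean of y_d approximates the mean per-plot residual
        # variance of the generating model
        assert tiny_dhglm.y_d.mean() == pytest.approx(
            truth.resid_var.mean(), rel=0.25)
        # and the fitted dispersion matches the mean of y_d closely
        fitted_mean = float(np.mean(1.0 / tiny_dhglm.w_mean))
        assert fitted_mean == pytest.approx(tiny_dhglm.y_d.mean(), rel=0.05)

    def test_mean_model_components_sane(self, tiny_dhglm, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        total = (tiny_dhglm.sigma2_g * tiny_dhglm.model.grm.mean_diagonal()
                 + tiny_dhglm.sigma2_l + tiny_dhglm.sigma2_f)
        truth_total = cfg.var_g * 1.9 + cfg.var_l + cfg.var_f
        assert total == pytest.approx(truth_total, rel=0.5)

    def test_summary_table(self, tiny_dhglm):
        tab = tiny_dhglm.summary()
        assert set(tab["parameter"]) >= {"sigma2_g", "sigma2_gd", "rho_g_gd"}
        assert np.isfinite(tab.loc[tab["parameter"] == "sigma2_g",
                                   "estimate"]).all()


class TestLogTransform:
    def test_scale_invariance_of_log_fit(self):
        cfg = SimConfig(n_lines=60, n_snps=400, n_envs=2, blocks_per_trial=3,
                        var_s=0.0, var_gd=0.02, rho=0.3, seed=77)
        pheno, geno, grm, truth = simulate_dataset(cfg)
        pheno["y_c"] = pheno["yield"]
        r1 = log_transform_refit(pheno, grm, corrected=None,
                                 response="yield")
        scaled = pheno.copy()
        scaled["yield"] = scaled["yield"] * 3.0
        r2 = log_transform_refit(scaled, grm, corrected=None,
                                 response="yield")
        assert np.allclose(r1.vc.estimates, r2.vc.estimates, atol=2e-3)
        # fixed effects shift by ln(c)
        assert np.isclose(r2.beta[0] - r1.beta[0], np.log(3.0), atol=0.05)

    def test_nonpositive_phenotype_rejected(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        bad = pheno.copy()
        bad["yield"] = bad["yield"] - bad["yield"].max() - 1.0
        with pytest.raises(ValueError, match="non-positive"):
            log_transform_refit(bad, grm, response="yield")
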