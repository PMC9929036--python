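import numpy as np
import pandas as pd
import pytest

from microsens.crossval import (bootstrap_se, corrected_line_means,
                                evaluate_model, loo_folds,
                                loo_predictions_lmm, max_potential_pa,
                                paired_bootstrap_test, paired_t_closed_form,
                                predictive_ability, whole_partial_stats)


class TestFolds:
    def test_partition_property(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        folds = loo_folds(pheno)
        assert len(folds) == pheno["line"].nunique()
        all_idx = np.concatenate(list(folds.values()))
        assert len(all_idx) == len(pheno)
        assert len(np.unique(all_idx)) == len(pheno)

    def test_fold_masks_all_line_plots(self, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        folds = loo_folds(pheno)
        lid, idx = next(iter(folds.items()))
        assert (pheno["line"].iloc[idx] == lid).all()
        assert (pheno["line"] == lid).sum() == len(idx)

    def test_too_few_lines(self):
        with pytest.raises(ValueError):
            loo_folds(pd.DataFrame({"line": ["a", "b"]}))


class TestLineMeans:
    def test_zero_fixed_effects_plain_mean(self):
        pheno = pd.DataFrame({"line": ["a", "a", "b"]})
        out = corrected_line_means(pheno, np.zeros(3), [1.0, 3.0, 5.0])
        assert out["a"] == 2.0 and out["b"] == 5.0

    def test_fixed_effect_shift_invariance(self):
        pheno = pd.DataFrame({"line": ["a", "a", "b"],
                              "trial": ["t1", "t2", "t1"]})
        y = np.array([1.0, 3.0, 5.0])
        fx = np.array([0.5, -0.2, 0.5])
        base = corrected_line_means(pheno, fx, y)
        shifted = corrected_line_means(pheno, fx + (pheno["trial"] == "t1"),
                                       y + (pheno["trial"] == "t1"))
        pd.testing.assert_series_equal(base, shifted)

    def test_averaging_beats_raw_plot_values(self, tiny_sim, tiny_lmm):
        cfg, pheno, geno, grm, truth = tiny_sim
        d = tiny_lmm.model.design
        fixed = d.X @ tiny_lmm.beta
        ybar = corrected_line_means(pheno, fixed, pheno["y_c"])
        pos = {lid: i for i, lid in enumerate(grm.line_ids)}
        target = truth.g + truth.l
        t_line = np.array([target[pos[lid]] for lid in ybar.index])
        r_mean = np.corrcoef(ybar.to_numpy(), t_line)[0, 1]
        t_plot = np.array([target[pos[lid]] for lid in pheno["line"]])
        r_plot = np.corrcoef(pheno["y_c"] - fixed, t_plot)[0, 1]
        assert r_mean > r_plot


class TestStatistics:
    def test_predictive_ability_trivial(self):
        v = np.array([1.0, 2.0, 4.0])
        assert predictive_ability(v, v) == pytest.approx(1.0)
        assert predictive_ability(v, -v) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            predictive_ability(v, np.ones(3))

    def test_whole_partial_trivial(self):
        w = np.array([1.0, 2.0, 4.0, 8.0])
        r, b = whole_partial_stats(w, w)
        assert (r, b) == (pytest.approx(1.0), pytest.approx(1.0))
        r, b = whole_partial_stats(w, w / 2.0)
        assert b == pytest.approx(2.0)

    def test_noise_attenuates_r_and_inflates_slope(self, rng):
        w = rng.standard_normal(300)
        rs, bs = [], []
        for _ in range(100):
            p = w + rng.normal(0, 0.5, 300)
            r, b = whole_partial_stats(w, p)
            rs.append(r)
            bs.append(b)
        assert np.mean(rs) < 1.0
        # var(p) > var(w) and cov = var(w) => slope < 1 on average;
        # regressing the clean signal on its noisy copy attenuates
        assert np.mean(bs) < 1.0
        r0, b0 = whole_partial_stats(w, w)
        assert np.mean(rs) < r0

    def test_max_potential_pa(self):
        assert max_potential_pa(1.0, 0.49) == pytest.approx(0.7)
        assert max_potential_pa(8.91, 0.033) == pytest.approx(0.483, abs=5e-4)
        assert max_potential_pa(5.0, 1.0) == pytest.approx(1.0)
        assert max_potential_pa(20.0, 0.2) > max_potential_pa(5.0, 0.2)
        with pytest.raises(ValueError):
            max_potential_pa(0.5, 0.2)


class TestBootstrap:
    def test_constant_statistic_zero_se(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        se, lo, hi = bootstrap_se(a, a, "corr", B=200, seed=0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_se_of_mean_oracle(self, rng):
        # bootstrap SE of a correlation-free statistic: use the slope of
        # y on x with x fixed unit variance ~ mean-like behavior; instead
        # directly check the mean via a degenerate pair
        x = rng.standard_normal(100)
        idx_se, *_ = bootstrap_se(x, np.arange(100, dtype=float), "slope",
                                  B=4000, seed=1)
        assert idx_se > 0

    def test_determinism_and_seed_sensitivity(self, rng):
        a = rng.standard_normal(80)
        b = a + rng.normal(0, 0.7, 80)
        se1, *_ = bootstrap_se(a, b, "corr", B=3000, seed=5)
        se2, *_ = bootstrap_se(a, b, "corr", B=3000, seed=5)
        se3, *_ = bootstrap_se(a, b, "corr", B=3000, seed=6)
        assert se1 == se2
        assert abs(se1 - se3) < 0.5 * se1 + 1e-3

    def test_b_too_small(self):
        with pytest.raises(ValueError):
            bootstrap_se([1.0, 2.0], [1.0, 2.0], B=1)


class TestPairedTests:
    def test_identical_models_p_one(self, rng):
        a = rng.standard_normal(50)
        b = a + rng.normal(0, 0.3, 50)
        t, p, sig = paired_bootstrap_test((a, b), (a, b), B=500, seed=0)
        assert (t, p, sig) == (0.0, 1.0, False)

    def test_clear_difference_significant(self, rng):
        x = rng.standard_normal(200)
        good = x + rng.normal(0, 0.1, 200)
        bad = x + rng.normal(0, 2.0, 200)
        t, p, sig = paired_bootstrap_test((x, good), (x, bad), B=2000, seed=1)
        assert sig and p < 1e-6

    def test_closed_form_oracle(self):
        d = np.array([0.3, -0.1, 0.4, 0.2, 0.0])
        t, p = paired_t_closed_form(d)
        n = len(d)
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        from scipy import stats
        p_ref = 2 * stats.t.sf(abs(t_ref), n - 1)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestDowndate:
    def test_downdate_equals_refit(self, tiny_lmm, tiny_sim):
        # the Woodbury downdate must match brute-force per-fold refits with
        # the same variance components
        cfg, pheno, geno, grm, truth = tiny_sim
        fast = loo_predictions_lmm(tiny_lmm, refit=False)
        from microsens.models import LMMHet
        pos = {lid: i for i, lid in enumerate(grm.line_ids)}
        for lid in list(fast.index)[:4]:
            sub = pheno[pheno["line"] != lid]
            model = LMMHet(sub, grm).build_model()
            sysm = model.assemble(tiny_lmm.vc.estimates)
            g_ref = sysm.term_solution("g")[pos[lid]]
            assert fast.loc[lid, "g_partial"] == pytest.approx(g_ref, abs=1e-8)

    def test_masked_line_phenotypes_do_not_leak(self, tiny_lmm, tiny_sim):
        cfg, pheno, geno, grm, truth = tiny_sim
        fast = loo_predictions_lmm(tiny_lmm, refit=False)
        lid = fast.index[0]
        # permuting the masked line's yields changes nothing in its fold
        permuted = pheno.copy()
        mask = permuted["line"] == lid
        vals = permuted.loc[mask, "y_c"].to_numpy()
        permuted.loc[mask, "y_c"] = vals[::-1] + 5.0
        from microsens.models import LMMHet
        sys2 = LMMHet(permuted, grm).build_model() \
            .assemble(tiny_lmm.vc.estimates)
        from microsens.crossval import _blup_downdate, _line_coef_ids
        pos = {l: i for i, l in enumerate(grm.line_ids)}
        fold_idx = np.where((pheno["line"] == lid).to_numpy())[0]
        cid = _line_coef_ids(sys2, "g", np.array([pos[lid]]))
        pred2 = _blup_downdate(sys2, fold_idx, cid)[0]
        assert pred2 == pytest.approx(fast.loc[lid, "g_partial"], abs=1e-8)


class TestEvaluateModel:
    def test_lmm_report(self, tiny_lmm):
        report = evaluate_model(tiny_lmm, "lmm_het", B=500, seed=0)
        assert report.n_folds == len(tiny_lmm.line_ids)
        assert -1.0 <= report.pa_g <= 1.0
        assert abs(report.r_wp_g) <= 1.0
        assert report.pa_g > 0.1          # real signal in the simulation
        assert 0.0 < report.max_pa_g <= 1.0
        d = report.as_dict()
        assert d["model_name"] == "lmm_het"

    def test_dhglm_report_completeness(self, tiny_dhglm):
        report = evaluate_model(tiny_dhglm, "dhglm", B=500, seed=0)
        assert report.pa_gd is not None
        assert -1.0 <= report.pa_gd <= 1.0
        assert abs(report.r_wp_gd) <= 1.0
        # the potential-PA bound respects the heritability ordering
        if report.extras["h2_d"] < 0.15:
            assert report.max_pa_gd <= report.max_pa_g
        assert report.b_wp_g == pytest.approx(1.0, abs=0.35)
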