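"""Leave-one-line-out cross-validation and predictive-performance statistics.

Model comparison follows the scheme used for genomic prediction of line
means: mask all plots of one line, predict its additive genetic values from
the remaining lines through the genomic relationships, and repeat for every
line.  Three statistics summarise performance:

PA      predictive ability, the Pearson correlation between fixed-effect
        corrected line means and the cross-validated predictions;
r_w,p   correlation between predictions from the whole data and from the
        partial (line-masked) data;
b_w,p   slope of the regression of whole-data predictions on partial-data
        predictions (1 = no inflation of prediction variance).

Uncertainty comes from a non-parametric bootstrap over lines; model
contrasts use a paired t-test on statistics recomputed per shared bootstrap
resample.

Fold predictions reuse the converged full-data variance components and
weights by default; each fold's BLUPs are then obtained by an exact Woodbury
downdate of the full mixed-model equations, identical to re-solving with the
line's observations removed.  A full per-fold re-estimation mode is
available for small problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ----------------------------------------------------------------------
# fold plans and line means
# ----------------------------------------------------------------------

def loo_folds(pheno: pd.DataFrame, line_col: str = "line") -> dict:
    """One fold per line: the fold masks every plot of that line."""
    lines = pd.unique(pheno[line_col])
    if len(lines) < 3:
        raise ValueError("need at least 3 lines for leave-one-line-out")
    idx = {lid: np.where(np.asarray(pheno[line_col]) == lid)[0]
           for lid in lines}
    return idx


def corrected_line_means(pheno: pd.DataFrame, fixed_values: np.ndarray,
                         response: np.ndarray,
                         line_col: str = "line") -> pd.Series:
    """Average response per line after subtracting per-plot fixed effects."""
    resp = np.asarray(response, float) - np.asarray(fixed_values, float)
    ser = pd.Series(resp).groupby(np.asarray(pheno[line_col])).mean()
    counts = pd.Series(resp).groupby(np.asarray(pheno[line_col])).size()
    empty = counts[counts == 0]
    if len(empty):  # pragma: no cover - groupby cannot produce empty groups
        import warnings
        warnings.warn(f"lines without plots excluded: {list(empty.index)}")
    return ser


# ----------------------------------------------------------------------
# statistics
# ----------------------------------------------------------------------

def predictive_ability(line_values, predictions) -> float:
    """Pearson correlation between corrected line means and predictions."""
    x = np.asarray(line_values, float)
    y = np.asarray(predictions, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("predictive ability undefined at zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def whole_partial_stats(g_whole, g_partial) -> tuple[float, float]:
    """(r_w,p, b_w,p): correlation and regression slope of whole-data
    predictions on partial-data predictions."""
    w = np.asarray(g_whole, float)
    p = np.asarray(g_partial, float)
    if len(w) != len(p) or len(w) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    var_p = np.var(p, ddof=1)
    if var_p == 0:
        raise ValueError("zero variance of partial predictions")
    r = float(np.corrcoef(w, p)[0, 1])
    b = float(np.cov(w, p, ddof=1)[0, 1] / var_p)
    return r, b


def _resample_matrix(n: int, B: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(B, n))


def _corr_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two B x n matrices."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _slope_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise slope of the regression of y on x."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    return (xc * yc).sum(axis=1) / (xc ** 2).sum(axis=1)


def bootstrap_se(values_a, values_b, statistic: str = "corr",
                 B: int = 10000, seed=0):
    """Bootstrap SE and normal 95% CI of a paired line-level statistic.

    Lines are resampled with replacement; the statistic ("corr" or "slope"
    of the regression of a on b) is recomputed per replicate; the SE is the
    SD over replicates and the CI is estimate +- 1.96 SE.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    idx = _resample_matrix(len(a), B, seed)
    if statistic == "corr":
        reps = _corr_rows(a[idx], b[idx])
        est = float(np.corrcoef(a, b)[0, 1])
    elif statistic == "slope":
        reps = _slope_rows(b[idx], a[idx])
        est = float(np.cov(a, b, ddof=1)[0, 1] / np.var(b, ddof=1))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    reps = reps[np.isfinite(reps)]
    se = float(np.std(reps, ddof=1))
    return se, est - 1.96 * se, est + 1.96 * se


def paired_bootstrap_test(pairs_a: tuple, pairs_b: tuple,
                          statistic: str = "corr", B: int = 10000, seed=0,
                          alpha: float = 0.01):
    """Two-tailed paired t-test of a statistic between two models.

    Both statistics are recomputed on identical bootstrap resamples of the
    lines; the per-replicate differences feed a one-sample t-test against 0.
    Returns (t, p_value, significant_at_alpha).
    """
    xa, ya = (np.asarray(v, float) for v in pairs_a)
    xb, yb = (np.asarray(v, float) for v in pairs_b)
    if len(xa) != len(xb):
        raise ValueError("both models must be evaluated on the same lines")
    idx = _resample_matrix(len(xa), B, seed)
    if statistic == "corr":
        ra = _corr_rows(xa[idx], ya[idx])
        rb = _corr_rows(xb[idx], yb[idx])
    elif statistic == "slope":
        ra = _slope_rows(xa[idx], ya[idx])
        rb = _slope_rows(xb[idx], yb[idx])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    d = ra - rb
    d = d[np.isfinite(d)]
    if np.allclose(d, 0.0):
        return 0.0, 1.0, False
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p), bool(p < alpha)


def paired_t_closed_form(differences) -> tuple[float, float]:
    """Textbook paired t-test on a vector of differences."""
    d = np.asarray(differences, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def max_potential_pa(k: float, h2: float) -> float:
    """Upper bound of predictive ability given k replicates at heritability
    h2: sqrt(k h2 / (1 + (k - 1) h2))."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    return float(np.sqrt(k * h2 / (1.0 + (k - 1.0) * h2)))


# ----------------------------------------------------------------------
# fold predictions by exact MME downdate
# ----------------------------------------------------------------------

def _blup_downdate(system, mask_rows: np.ndarray, coef_ids: np.ndarray):
    """BLUP entries after removing observations, via Woodbury downdate.

    Exactly equals re-solving the mixed-model equations with the rows in
    ``mask_rows`` deleted (variance components kept fixed).  ``coef_ids``
    selects the coefficients whose downdated solutions are returned.
    """
    TX = system.TX.tocsr()
    U = TX[mask_rows]                      # m x ncoef, sparse
    r_m = 1.0 / system.rinv[mask_rows]     # residual variances of masked rows
    y_m = system.y[mask_rows]
    support = np.unique(U.indices)
    Ud = np.asarray(U[:, support].todense())
    # C^{-1} over the union of masked-row support and requested coefficients
    all_ids = np.unique(np.concatenate([support, coef_ids]))
    Cinv = system.cinv_submatrix(all_ids)
    pos = {c: i for i, c in enumerate(all_ids)}
    sup_pos = np.array([pos[c] for c in support])
    coef_pos = np.array([pos[c] for c in coef_ids])
    Cs = Cinv[np.ix_(sup_pos, sup_pos)]
    H_m = Ud @ Cs @ Ud.T                             # U C^{-1} U'
    K = np.diag(r_m) - H_m
    sol_m = system.sol  # full solutions
    yhat_m = np.asarray(U @ sol_m).ravel()
    rhs1 = y_m / r_m
    # sol' = sol - C^{-1}U'[ rhs1 - K^{-1}(U sol - H_m rhs1 + ... ) ]
    # derive: sol' = sol - A rhs1 + A K^{-1} (yhat_m - H_m rhs1)
    #   with A = C^{-1} U'
    adj = np.linalg.solve(K, yhat_m - H_m @ rhs1)
    w = rhs1 - adj
    A_coef = Cinv[np.ix_(coef_pos, sup_pos)] @ Ud.T  # rows: coef, cols: m
    return sol_m[coef_ids] - A_coef @ w


@dataclass
class CVReport:
    """Cross-validation summary for one fitted model."""

    model_name: str
    pa_g: float
    pa_gd: float | None
    r_wp_g: float
    b_wp_g: float
    r_wp_gd: float | None
    b_wp_gd: float | None
    pa_g_se: float
    r_wp_g_se: float
    b_wp_g_se: float
    max_pa_g: float
    max_pa_gd: float | None
    n_folds: int
    predictions: pd.DataFrame = field(repr=False)
    extras: dict = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict:
        out = {k: (None if v is None or (isinstance(v, float) and np.isnan(v))
                   else float(v))
               for k, v in self.__dict__.items()
               if k not in ("predictions", "extras", "model_name", "n_folds")}
        out["model_name"] = self.model_name
        out["n_folds"] = int(self.n_folds)
        out.update({k: float(v) for k, v in self.extras.items()})
        return out


def _line_coef_ids(system, term: str, line_positions: np.ndarray,
                   offset: int = 0) -> np.ndarray:
    a, _ = system.col_offsets[term]
    return a + offset + line_positions


def loo_predictions_lmm(results, refit: bool = False) -> pd.DataFrame:
    """Per-line LOO predictions of g for an LMM-HET fit.

    ``refit=False`` (default) reuses the full-data variance components and
    downdates the equations per fold; ``refit=True`` re-estimates variance
    components per fold (slow, small problems only).
    """
    model = results.model
    pheno = model.pheno
    grm = model.grm
    folds = loo_folds(pheno)
    line_ids = list(grm.line_ids)
    line_pos = {lid: i for i, lid in enumerate(line_ids)}
    rows = []
    if refit:
        from .models import LMMHet
        for lid, mask in folds.items():
            sub = pheno.drop(index=pheno.index[mask])
            res_f = LMMHet(sub, grm, response=model.response).fit()
            rows.append((lid, res_f.g_hat[line_pos[lid]]))
    else:
        system = results.reml.system
        for lid, mask in folds.items():
            cid = _line_coef_ids(system, "g", np.array([line_pos[lid]]))
            g_part = _blup_downdate(system, mask, cid)
            rows.append((lid, float(g_part[0])))
    return pd.DataFrame(rows, columns=["line", "g_partial"]).set_index("line")


def loo_predictions_dhglm(results, refit: bool = False) -> pd.DataFrame:
    """Per-line LOO predictions of g and g_d for a DHGLM fit.

    Masking a line removes both its mean-model rows and its dispersion-model
    rows (all information from the line's phenotypes); weights and variance
    components stay at their full-data converged values unless ``refit``.
    """
    model = results.model
    pheno = model.pheno
    grm = model.grm
    n = model.n_obs
    folds = loo_folds(pheno)
    line_pos = {lid: i for i, lid in enumerate(grm.line_ids)}
    nl = grm.n_lines
    rows = []
    if refit:  # pragma: no cover - exercised only on tiny problems
        from .models import DHGLM
        for lid, mask in folds.items():
            sub = pheno.drop(index=pheno.index[mask])
            res_f = DHGLM(sub, grm, response=model.response).fit()
            p = line_pos[lid]
            rows.append((lid, res_f.g_hat[p], res_f.gd_hat[p]))
    else:
        system = results.reml.system
        for lid, mask in folds.items():
            both = np.concatenate([mask, mask + n])
            p = line_pos[lid]
            cid = _line_coef_ids(system, "gbiv", np.array([p, nl + p]))
            sol = _blup_downdate(system, both, cid)
            rows.append((lid, float(sol[0]), float(sol[1])))
    return pd.DataFrame(rows, columns=["line", "g_partial", "gd_partial"]) \
        .set_index("line")


def evaluate_model(results, model_name: str, B: int = 10000, seed: int = 0,
                   refit: bool = False) -> CVReport:
    """Full LOO evaluation of an LMM-HET or DHGLM fit."""
    from .models import DHGLMResults, LMMHetResults

    model = results.model
    pheno = model.pheno
    d = model.design
    is_dhglm = isinstance(results, DHGLMResults)
    yvec = np.asarray(pheno[model.response], float)
    fixed_mean = d.X @ (results.beta if is_dhglm else results.reml.beta[: d.X.shape[1]])
    ybar_c = corrected_line_means(pheno, fixed_mean, yvec)
    line_ids = list(model.grm.line_ids)
    g_whole = pd.Series(results.g_hat, index=line_ids)

    if is_dhglm:
        preds = loo_predictions_dhglm(results, refit=refit)
        gd_whole = pd.Series(results.gd_hat, index=line_ids)
        fixed_disp = d.X @ results.beta_d
        ybar_d = corrected_line_means(pheno, fixed_disp,
                                      results.working_response)
    else:
        preds = loo_predictions_lmm(results, refit=refit)
        gd_whole = None
        ybar_d = None

    common = [lid for lid in preds.index if lid in ybar_c.index]
    gp = preds.loc[common, "g_partial"].to_numpy()
    gw = g_whole.loc[common].to_numpy()
    yc = ybar_c.loc[common].to_numpy()

    pa_g = predictive_ability(yc, gp)
    r_wp, b_wp = whole_partial_stats(gw, gp)
    pa_se, *_ = bootstrap_se(yc, gp, "corr", B=B, seed=seed)
    r_se, *_ = bootstrap_se(gw, gp, "corr", B=B, seed=seed + 1)
    b_se, *_ = bootstrap_se(gw, gp, "slope", B=B, seed=seed + 2)

    # maximum potential PA from per-environment heritabilities and the
    # average line replication per environment
    if is_dhglm:
        sig_e = results.sigma2_e_by_env()
    else:
        sig_e = results.sigma2_e_by_env()
    reps = pheno.groupby("env")["line"].value_counts().groupby("env").mean()
    from .genpar import heritability_plot
    max_pas = []
    h2s = {}
    for env in d.env_levels:
        _, h2, _ = heritability_plot(results.sigma2_g, results.sigma2_l,
                                     results.sigma2_f, sig_e[env])
        h2s[env] = h2
        max_pas.append(max_potential_pa(float(reps[env]), h2))
    max_pa_g = float(np.mean(max_pas))

    pa_gd = r_wp_gd = b_wp_gd = max_pa_gd = None
    extras = {}
    if is_dhglm:
        gdp = preds.loc[common, "gd_partial"].to_numpy()
        gdw = gd_whole.loc[common].to_numpy()
        yd = ybar_d.loc[common].to_numpy()
        pa_gd = predictive_ability(yd, gdp)
        r_wp_gd, b_wp_gd = whole_partial_stats(gdw, gdp)
        from .genpar import genetic_params_from_fit
        gpars = genetic_params_from_fit(results)
        k_mean = float(pheno.groupby("line").size().mean())
        max_pa_gd = max_potential_pa(k_mean, gpars.h2_d)
        extras["h2_d"] = gpars.h2_d

    pred_out = preds.copy()
    pred_out["g_whole"] = g_whole.loc[preds.index].to_numpy()
    pred_out["ybar_c"] = ybar_c.reindex(preds.index).to_numpy()
    return CVReport(
        model_name=model_name, pa_g=pa_g, pa_gd=pa_gd, r_wp_g=r_wp,
        b_wp_g=b_wp, r_wp_gd=r_wp_gd, b_wp_gd=b_wp_gd, pa_g_se=pa_se,
        r_wp_g_se=r_se, b_wp_g_se=b_se, max_pa_g=max_pa_g,
        max_pa_gd=max_pa_gd, n_folds=len(preds), predictions=pred_out,
        extras=extras)
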