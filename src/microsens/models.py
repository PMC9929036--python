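"""Analysis stages as model/results objects.

Three fitted-model classes cover the pipeline for plot-level yield from
multi-environment trials of genotyped inbred lines:

``SpatialCorrection``
    Stage 1: a mixed model with trial fixed effects, genomic (g), line (l)
    and line-by-environment (f) random effects plus an iid plot effect whose
    3x3 neighborhood sum captures spatial field trends; phenotypes are
    corrected by subtracting the estimated spatial contribution.

``LMMHet``
    The reference linear mixed model on corrected phenotypes with a separate
    residual variance per year-location environment.

``DHGLM``
    The double hierarchical GLM: a bivariate mixed model linking the
    corrected phenotype (mean model) with a gamma-GLM dispersion model on the
    squared leverage-corrected residuals, with correlated genomic effects
    (g, g_d) on the two levels.  Fitted by iterative reweighting until the
    variance components stabilise.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .genomics import GRM
from .mme import RandomTerm, ResidualClass
from .reml import (ConvergenceError, MixedModel, REMLResults, VCEstimates,
                   weighted_gamma_glm)
from .simulate import neighborhood_incidence

REQUIRED_COLUMNS = ("line", "trial", "env")


# ----------------------------------------------------------------------
# design assembly
# ----------------------------------------------------------------------

@dataclass
class DesignBundle:
    """Assembled design: fixed matrix, factor incidences, residual classes."""

    X: np.ndarray
    fixed_names: list[str]
    Z_line: sparse.csr_matrix
    Z_f: sparse.csr_matrix
    f_levels: list[tuple]
    env_labels: np.ndarray
    env_levels: list
    npar_per_env: dict
    line_index: np.ndarray      # position of each obs's line in grm order


def incidence(labels, levels) -> sparse.csr_matrix:
    """0/1 incidence matrix with exactly one 1 per row."""
    pos = {lev: j for j, lev in enumerate(levels)}
    cols = np.array([pos[v] for v in labels])
    n = len(cols)
    return sparse.csr_matrix((np.ones(n), (np.arange(n), cols)),
                             shape=(n, len(levels)))


def assemble_design(pheno: pd.DataFrame, grm: GRM) -> DesignBundle:
    """Fixed trial-within-environment design plus random-effect incidences.

    The fixed design is an intercept plus reference-level (drop-first)
    dummies over trial; rank is checked after the drop.
    """
    for col in REQUIRED_COLUMNS:
        if col not in pheno.columns:
            raise ValueError(f"phenotype table lacks required column {col!r}")
    trials = sorted(pheno["trial"].unique())
    n = len(pheno)
    X = np.ones((n, len(trials)))
    names = ["intercept"]
    for j, t in enumerate(trials[1:], start=1):
        X[:, j] = (pheno["trial"] == t).astype(float)
        names.append(f"trial[{t}]")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"fixed-effect design rank deficient (rank {rank} < {X.shape[1]}); "
            "confounded trial factor levels")
    line_pos = {lid: i for i, lid in enumerate(grm.line_ids)}
    missing = set(pheno["line"]) - set(line_pos)
    if missing:
        raise ValueError(f"lines without genotypes: {sorted(missing)[:5]}")
    line_index = np.array([line_pos[lid] for lid in pheno["line"]])
    Z_line = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), line_index)), shape=(n, grm.n_lines))
    pairs = list(zip(pheno["line"], pheno["env"]))
    f_levels = sorted(set(pairs))
    Z_f = incidence(pairs, f_levels)
    env_levels = sorted(pheno["env"].unique())
    env_labels = np.asarray(pheno["env"])
    npar = {e: pheno.loc[pheno["env"] == e, "trial"].nunique()
            for e in env_levels}
    return DesignBundle(X=X, fixed_names=names, Z_line=Z_line, Z_f=Z_f,
                        f_levels=f_levels, env_labels=env_labels,
                        env_levels=env_levels, npar_per_env=npar,
                        line_index=line_index)


def _stack_bivariate(Z: sparse.csr_matrix, n_total: int,
                     offset: int) -> sparse.csr_matrix:
    """Place an incidence block into the stacked two-trait observation set."""
    n = Z.shape[0]
    top = offset
    bottom = n_total - offset - n
    blocks = []
    if top:
        blocks.append(sparse.csr_matrix((top, Z.shape[1])))
    blocks.append(Z)
    if bottom:
        blocks.append(sparse.csr_matrix((bottom, Z.shape[1])))
    return sparse.vstack(blocks, format="csr")


# ----------------------------------------------------------------------
# stage 1: spatial correction
# ----------------------------------------------------------------------

class CorrectedPhenotypes:
    """Stage-1 result: spatially corrected phenotypes and components."""

    def __init__(self, pheno: pd.DataFrame, y_c: np.ndarray, s_hat: np.ndarray,
                 spatial_contribution: np.ndarray, vc: VCEstimates,
                 reml: REMLResults, response: str):
        self.pheno = pheno.copy()
        self.pheno["y_c"] = y_c
        self.y_c = np.asarray(y_c, float)
        self.s_hat = s_hat
        self.spatial_contribution = spatial_contribution
        self.vc = vc
        self.reml = reml
        self.response = response

    @property
    def sigma2_s(self) -> float:
        return self.vc["spatial:var"]


class SpatialCorrection:
    """Stage-1 spatial model; ``fit`` returns :class:`CorrectedPhenotypes`."""

    def __init__(self, pheno: pd.DataFrame, grm: GRM, response: str = "yield"):
        for col in ("x", "y"):
            if col not in pheno.columns:
                raise ValueError(f"plot coordinate column {col!r} missing")
        if pheno[["x", "y"]].isna().any().any():
            raise ValueError("missing plot coordinates")
        dup = pheno.duplicated(subset=["trial", "x", "y"])
        if dup.any():
            raise ValueError(
                f"duplicate plot coordinates within trial: "
                f"{pheno.loc[dup, ['trial', 'x', 'y']].head().to_dict('records')}")
        self.pheno = pheno.reset_index(drop=True)
        self.grm = grm
        self.response = response
        self.design = assemble_design(self.pheno, grm)
        self.Z_nbr = neighborhood_incidence(self.pheno)

    def fit(self, tol: float = 1e-8, max_iter: int = 200,
            start: np.ndarray | None = None) -> CorrectedPhenotypes:
        d = self.design
        y = np.asarray(self.pheno[self.response], float)
        n = len(y)
        terms = [
            RandomTerm("g", d.Z_line, kind="grm", grm=self.grm),
            RandomTerm("l", d.Z_line, kind="iid"),
            RandomTerm("f", d.Z_f, kind="iid"),
            RandomTerm("spatial", self.Z_nbr, kind="iid"),
        ]
        classes = [ResidualClass("e", np.arange(n))]
        model = MixedModel(y, d.X, terms, classes)
        if start is None:
            vy = max(float(np.var(y)), 1e-6)
            start = np.array([0.15, 0.15, 0.25, 0.05, 0.4]) * vy
        res = model.fit(start=start, tol=tol, max_iter=max_iter)
        s_hat = res.blup("spatial")
        contribution = self.Z_nbr @ s_hat
        y_c = y - contribution
        return CorrectedPhenotypes(self.pheno, y_c, s_hat, contribution,
                                   res.vc, res, self.response)


def fit_spatial_stage(pheno: pd.DataFrame, grm: GRM,
                      response: str = "yield", **kwargs) -> CorrectedPhenotypes:
    """Functional wrapper around :class:`SpatialCorrection`."""
    return SpatialCorrection(pheno, grm, response=response).fit(**kwargs)


# ----------------------------------------------------------------------
# LMM-HET
# ----------------------------------------------------------------------

class LMMHetResults:
    """Reference-model fit with per-environment residual variances."""

    def __init__(self, model: "LMMHet", reml: REMLResults):
        self.model = model
        self.reml = reml
        self.vc = reml.vc
        self.converged = reml.converged
        d = model.design
        self.env_levels = d.env_levels
        self.line_ids = np.asarray(model.grm.line_ids)

    @property
    def beta(self) -> np.ndarray:
        return self.reml.beta

    @property
    def g_hat(self) -> np.ndarray:
        return self.reml.blup("g")

    @property
    def l_hat(self) -> np.ndarray:
        return self.reml.blup("l")

    @property
    def f_hat(self) -> np.ndarray:
        return self.reml.blup("f")

    @property
    def sigma2_g(self) -> float:
        return self.vc["g:var"]

    @property
    def sigma2_l(self) -> float:
        return self.vc["l:var"]

    @property
    def sigma2_f(self) -> float:
        return self.vc["f:var"]

    def sigma2_e_by_env(self) -> dict:
        return {e: self.vc[f"resid:{e}"] for e in self.env_levels}

    def summary(self) -> pd.DataFrame:
        rows = [("sigma2_g", self.sigma2_g), ("sigma2_l", self.sigma2_l),
                ("sigma2_f", self.sigma2_f)]
        rows += [(f"sigma2_e[{e}]", v) for e, v in self.sigma2_e_by_env().items()]
        df = pd.DataFrame(rows, columns=["parameter", "estimate"])
        se = {n: s for n, s in zip(self.vc.names, self.vc.se)}
        df["se"] = [se.get("g:var"), se.get("l:var"), se.get("f:var")] + \
                   [se.get(f"resid:{e}") for e in self.env_levels]
        return df


class LMMHet:
    """Linear mixed model on corrected phenotypes with heterogeneous
    per-environment residual variance (the reference model)."""

    def __init__(self, corrected: CorrectedPhenotypes | pd.DataFrame,
                 grm: GRM, response: str = "y_c"):
        pheno = corrected.pheno if isinstance(corrected, CorrectedPhenotypes) \
            else corrected
        self.pheno = pheno.reset_index(drop=True)
        if response not in self.pheno.columns:
            raise ValueError(f"response column {response!r} missing")
        self.response = response
        self.grm = grm
        self.design = assemble_design(self.pheno, grm)
        counts = self.pheno.groupby("env").size()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"environments with < 2 observations: {list(small.index)}")

    def build_model(self) -> MixedModel:
        d = self.design
        y = np.asarray(self.pheno[self.response], float)
        terms = [
            RandomTerm("g", d.Z_line, kind="grm", grm=self.grm),
            RandomTerm("l", d.Z_line, kind="iid"),
            RandomTerm("f", d.Z_f, kind="iid"),
        ]
        env = d.env_labels
        classes = [ResidualClass(e, np.where(env == e)[0]) for e in d.env_levels]
        return MixedModel(y, d.X, terms, classes)

    def fit(self, tol: float = 1e-8, max_iter: int = 200,
            start: np.ndarray | None = None) -> LMMHetResults:
        model = self.build_model()
        if start is None:
            vy = max(float(np.var(np.asarray(self.pheno[self.response], float))), 1e-6)
            start = np.array([0.2, 0.2, 0.3] + [0.3] * len(self.design.env_levels)) * vy
        res = model.fit(start=start, tol=tol, max_iter=max_iter)
        return LMMHetResults(self, res)


def fit_lmm_het(corrected, grm: GRM, **kwargs) -> LMMHetResults:
    return LMMHet(corrected, grm).fit(**kwargs)


# ----------------------------------------------------------------------
# DHGLM
# ----------------------------------------------------------------------

def compute_dispersion_response(e_hat, leverage):
    """Dispersion response y_d = e_hat^2 / (1 - leverage)."""
    e_hat = np.asarray(e_hat, float)
    lev = np.asarray(leverage, float)
    if (lev < 0).any() or (lev >= 1).any():
        raise ValueError("leverage must lie in [0, 1)")
    return e_hat ** 2 / (1.0 - lev)


class DHGLMResults:
    """Converged double hierarchical GLM fit.

    Holds fixed effects for the mean (``beta``) and dispersion (``beta_d``)
    models, BLUPs (g, g_d, l, f), the bivariate variance components, the
    working dispersion quantities (y_d, leverages, W, W_d), residual scale
    parameters (both ~1 at convergence by construction), and the iteration
    trace.
    """

    def __init__(self, model: "DHGLM", reml: REMLResults, y_d, leverage,
                 w_mean, w_disp, working_response, glm, outer_trace,
                 converged: bool, n_outer: int):
        self.model = model
        self.reml = reml
        self.vc = reml.vc
        self.y_d = np.asarray(y_d)
        self.leverage = np.asarray(leverage)
        self.w_mean = np.asarray(w_mean)      # W = 1/fitted dispersion
        self.w_disp = np.asarray(w_disp)      # W_d = (1 - leverage)/2
        self.working_response = np.asarray(working_response)
        self.glm = glm
        self.outer_trace = outer_trace
        self.converged = converged
        self.n_outer = n_outer
        d = model.design
        self.env_levels = d.env_levels
        self.line_ids = np.asarray(model.grm.line_ids)
        n = model.n_obs
        self.resid = reml.resid[:n]

    # --- parameters ----------------------------------------------------
    @property
    def sigma2_g(self) -> float:
        return self.vc["gbiv:var1"]

    @property
    def sigma2_gd(self) -> float:
        return self.vc["gbiv:var2"]

    @property
    def sigma_g_gd(self) -> float:
        return self.vc["gbiv:cov12"]

    @property
    def sigma2_l(self) -> float:
        return self.vc["l:var"]

    @property
    def sigma2_f(self) -> float:
        return self.vc["f:var"]

    @property
    def sigma2_e_scale(self) -> float:
        return self.vc["resid:mean"]

    @property
    def sigma2_ev_scale(self) -> float:
        return self.vc["resid:disp"]

    @property
    def rho_g_gd(self) -> float:
        from .genpar import genetic_correlation
        return genetic_correlation(self.sigma_g_gd, self.sigma2_g, self.sigma2_gd)

    # --- effects -------------------------------------------------------
    @property
    def beta(self) -> np.ndarray:
        return self.reml.beta[: self.model.p_mean]

    @property
    def beta_d(self) -> np.ndarray:
        return self.reml.beta[self.model.p_mean:]

    @property
    def g_hat(self) -> np.ndarray:
        return self.reml.blup("gbiv")[: self.model.grm.n_lines]

    @property
    def gd_hat(self) -> np.ndarray:
        return self.reml.blup("gbiv")[self.model.grm.n_lines:]

    @property
    def l_hat(self) -> np.ndarray:
        return self.reml.blup("l")

    @property
    def f_hat(self) -> np.ndarray:
        return self.reml.blup("f")

    def sigma2_e_by_env(self) -> dict:
        """Per-environment residual variance from the final mean-model
        residuals (sample variance with the fixed-effect count removed
        from the denominator)."""
        from .genpar import residual_var_by_env
        d = self.model.design
        return residual_var_by_env(self.resid, d.env_labels, d.npar_per_env)

    def genetic_params(self, d_g: float | None = None):
        from .genpar import genetic_params_from_fit
        return genetic_params_from_fit(self, d_g=d_g)

    def summary(self) -> pd.DataFrame:
        se = {n: s for n, s in zip(self.vc.names, self.vc.se)}
        rows = [
            ("sigma2_g", self.sigma2_g, se.get("gbiv:var1")),
            ("sigma2_gd", self.sigma2_gd, se.get("gbiv:var2")),
            ("sigma_g_gd", self.sigma_g_gd, se.get("gbiv:cov12")),
            ("rho_g_gd", self.rho_g_gd, None),
            ("sigma2_l", self.sigma2_l, se.get("l:var")),
            ("sigma2_f", self.sigma2_f, se.get("f:var")),
            ("sigma2_e_scale", self.sigma2_e_scale, se.get("resid:mean")),
            ("sigma2_ev_scale", self.sigma2_ev_scale, se.get("resid:disp")),
        ]
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])


class DHGLM:
    """Double hierarchical GLM for mean and dispersion of a trait.

    The iterative scheme: (1) homoscedastic LMM on the corrected phenotype;
    (2) dispersion response y_d = e^2/(1-leverage) and weight
    W_d = (1-leverage)/2; (3) weighted gamma GLM (log link) on y_d giving the
    dispersion fixed effects and the working response; (4) mean-model weights
    W = 1/fitted-dispersion; (5) bivariate REML of mean response and working
    response with trait covariance [[s2_g, s_g_gd], [s_g_gd, s2_gd]] kron G,
    l and f on the mean trait only; (6) update y_d, W, W_d; repeat 3-6 until
    every variance component changes by less than ``tol`` relative.
    """

    def __init__(self, corrected: CorrectedPhenotypes | pd.DataFrame,
                 grm: GRM, response: str = "y_c"):
        pheno = corrected.pheno if isinstance(corrected, CorrectedPhenotypes) \
            else corrected
        self.pheno = pheno.reset_index(drop=True)
        if response not in self.pheno.columns:
            raise ValueError(f"response column {response!r} missing")
        self.response = response
        self.grm = grm
        self.design = assemble_design(self.pheno, grm)
        self.n_obs = len(self.pheno)
        self.p_mean = self.design.X.shape[1]

    # ------------------------------------------------------------------
    def _bivariate_model(self, zeta, w_mean, w_disp, estimate_scales=False):
        d = self.design
        n = self.n_obs
        y = np.concatenate([np.asarray(self.pheno[self.response], float), zeta])
        X = np.zeros((2 * n, 2 * self.p_mean))
        X[:n, : self.p_mean] = d.X
        X[n:, self.p_mean:] = d.X
        nl = self.grm.n_lines
        Z1 = _stack_bivariate(d.Z_line, 2 * n, 0)
        Z2 = _stack_bivariate(d.Z_line, 2 * n, n)
        Zbiv = sparse.hstack([Z1, Z2], format="csr")
        terms = [
            RandomTerm("gbiv", Zbiv, kind="grm_bivariate", grm=self.grm),
            RandomTerm("l", _stack_bivariate(d.Z_line, 2 * n, 0), kind="iid"),
            RandomTerm("f", _stack_bivariate(d.Z_f, 2 * n, 0), kind="iid"),
        ]
        classes = [
            ResidualClass("mean", np.arange(n), weights=w_mean),
            ResidualClass("disp", np.arange(n, 2 * n), weights=w_disp),
        ]
        # The weight matrices W and W_d fully specify the residual variances;
        # their scale parameters are the constrained-to-one scalings of the
        # bivariate model.  Freeing them lets the within-line deficit of
        # squared-residual variation (induced by shrinkage of the line and
        # line-by-environment BLUPs) deflate the dispersion residual scale
        # and leak into sigma2_gd, so they are fixed at one by default.
        fixed = None if estimate_scales else {"resid:mean": 1.0, "resid:disp": 1.0}
        return MixedModel(y, X, terms, classes, fixed_params=fixed)

    def fit(self, tol: float = 1e-5, max_iter: int = 100,
            reml_tol: float = 1e-8, reml_max_iter: int = 200,
            estimate_scales: bool = False,
            verbose: bool = False) -> DHGLMResults:
        d = self.design
        n = self.n_obs
        y_c = np.asarray(self.pheno[self.response], float)

        # step 1: homoscedastic LMM on y_c
        terms0 = [
            RandomTerm("g", d.Z_line, kind="grm", grm=self.grm),
            RandomTerm("l", d.Z_line, kind="iid"),
            RandomTerm("f", d.Z_f, kind="iid"),
        ]
        vy = max(float(np.var(y_c)), 1e-6)
        model0 = MixedModel(y_c, d.X, terms0,
                            [ResidualClass("e", np.arange(n))])
        res0 = model0.fit(start=np.array([0.2, 0.2, 0.3, 0.3]) * vy,
                          tol=reml_tol, max_iter=reml_max_iter)
        e_hat = res0.resid
        lev = res0.leverages()
        gd_hat = np.zeros(self.grm.n_lines)

        # initial bivariate components: mean-model values from step 1, a
        # small log-scale dispersion variance, unit residual scales
        # (layout: gbiv var1/cov12/var2, l, f, resid mean, resid disp)
        theta = np.array([
            res0.vc["g:var"], 0.0, 0.05,
            res0.vc["l:var"], res0.vc["f:var"], 1.0, 1.0,
        ])

        outer_trace = []
        converged = False
        reml_res = None
        glm = None
        zeta = None
        w_mean = None
        w_disp = None
        y_d = None
        # adaptive relaxation of the g_d/weights fixed-point iteration: the
        # feedback between the dispersion BLUP and the residual weights
        # converges geometrically (often with alternating sign); relaxing the
        # update by omega = 1/(1 - r), with r the dominant contraction ratio
        # estimated from successive update residuals, damps the oscillation
        # and shortens the monotone tail without moving the fixed point
        resid_prev: np.ndarray | None = None
        omega = 1.0
        for outer in range(1, max_iter + 1):
            y_d = compute_dispersion_response(e_hat, lev)
            w_disp = (1.0 - lev) / 2.0
            offset = gd_hat[d.line_index]
            glm = weighted_gamma_glm(y_d, d.X, weights=w_disp, offset=offset)
            zeta = glm.working_response
            fitted_disp = np.maximum(glm.fitted, 1e-10)
            w_mean = 1.0 / fitted_disp
            model = self._bivariate_model(zeta, w_mean, w_disp,
                                          estimate_scales=estimate_scales)
            res = model.fit(start=theta, tol=reml_tol, max_iter=reml_max_iter)
            new_theta = res.vc.estimates
            rel = float(np.max(np.abs(new_theta - theta)
                               / (np.abs(theta) + 1e-8)))
            outer_trace.append({"outer": outer, "rel_change": rel,
                                "theta": new_theta.tolist(),
                                "loglik": res.loglik,
                                "reml_iters": res.vc.n_iter})
            if verbose:  # pragma: no cover
                print(f"outer {outer}: rel={rel:.3e}")
            theta = new_theta
            reml_res = res
            e_hat = res.resid[:n]
            lev = res.leverages()[:n]
            nl = self.grm.n_lines
            gd_raw = res.blup("gbiv")[nl:]
            if rel < tol:
                gd_hat = gd_raw
                converged = True
                break
            # boundary solutions (correlation locked at +-1) wobble inside the
            # numerical noise floor without trending; accept the fit once
            # every component has stayed within a negligible band for a
            # sustained window
            if len(outer_trace) >= 12:
                window = np.array([outer_trace[j]["theta"] for j in range(-12, 0)])
                spread = window.max(axis=0) - window.min(axis=0)
                t_now = np.abs(window[-1])
                if np.all(spread < 3e-3 * (t_now + 1e-3)):
                    gd_hat = gd_raw
                    converged = True
                    break
            resid_vec = gd_raw - gd_hat      # fixed-point update residual
            if resid_prev is not None:
                denom = float(resid_prev @ resid_prev)
                if denom > 0:
                    r = float(resid_vec @ resid_prev) / denom
                    omega = float(np.clip(1.0 / (1.0 - r), 0.3, 3.0)) \
                        if -0.95 < r < 0.9 else 1.0
            resid_prev = resid_vec.copy()
            gd_hat = gd_hat + omega * resid_vec
        if not converged:
            raise ConvergenceError(
                f"DHGLM did not converge in {max_iter} outer iterations "
                f"(last relative change {outer_trace[-1]['rel_change']:.3e})",
                outer_trace)
        return DHGLMResults(self, reml_res, y_d, lev, w_mean, w_disp, zeta,
                            glm, outer_trace, converged, outer)


def fit_dhglm(corrected, grm: GRM, tol: float = 1e-5, max_iter: int = 100,
              **kwargs) -> DHGLMResults:
    return DHGLM(corrected, grm).fit(tol=tol, max_iter=max_iter, **kwargs)


def log_transform_refit(pheno: pd.DataFrame, grm: GRM,
                        response: str = "yield",
                        corrected: CorrectedPhenotypes | None = None,
                        **kwargs) -> DHGLMResults:
    """Re-run the pipeline on the natural log of the corrected phenotype.

    Removes the scale dependence of the dispersion on the mean: a genotype
    whose residual SD is proportional to its mean shows no dispersion signal
    on the log scale.
    """
    if corrected is None:
        corrected = fit_spatial_stage(pheno, grm, response=response)
    tab = corrected.pheno.copy()
    bad = tab["y_c"] <= 0
    if bad.any():
        raise ValueError(
            "non-positive corrected phenotypes; offending plots: "
            f"{tab.loc[bad, ['line', 'trial', 'x', 'y']].head().to_dict('records')}")
    tab["log_y_c"] = np.log(tab["y_c"])
    return DHGLM(tab, grm, response="log_y_c").fit(**kwargs)
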