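"""Genetic parameters for micro-environmental sensitivity.

Derived quantities from a converged fit: per-environment phenotypic variance
and plot-level heritabilities, the exponential-to-additive scale conversion
of the dispersion genetic variance, the Mulder-Hill heritability of residual
variance h2_d, the genomic coefficient of variation of residual variance
GCV_E (evolvability), and the genetic correlation rho_g,gd between additive
effects on the expressed trait and on its dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GeneticParams:
    """Bundle of genetic parameters with their per-environment detail."""

    per_env: pd.DataFrame          # sigma2_e, sigma2_P, h2, H2 per environment
    sigma2_g: float
    sigma2_gd: float
    sigma_g_gd: float
    rho_g_gd: float
    sigma2_e_add: float
    sigma2_e_exp: float
    sigma2_gd_add: float
    h2_d: float
    gcv_e: float
    d_g: float
    variant: str = "reported-scale"

    def summary(self) -> pd.DataFrame:
        rows = [
            ("mean_h2", self.per_env["h2"].mean()),
            ("mean_H2", self.per_env["H2"].mean()),
            ("mean_sigma2_P", self.per_env["sigma2_P"].mean()),
            ("sigma2_gd (log scale)", self.sigma2_gd),
            ("sigma2_gd_add", self.sigma2_gd_add),
            ("h2_d", self.h2_d),
            ("GCV_E", self.gcv_e),
            ("rho_g_gd", self.rho_g_gd),
            ("d(G)", self.d_g),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value"])

    def as_dict(self) -> dict:
        out = {
            "sigma2_g": self.sigma2_g, "sigma2_gd": self.sigma2_gd,
            "sigma_g_gd": self.sigma_g_gd, "rho_g_gd": self.rho_g_gd,
            "sigma2_e_add": self.sigma2_e_add, "sigma2_e_exp": self.sigma2_e_exp,
            "sigma2_gd_add": self.sigma2_gd_add, "h2_d": self.h2_d,
            "gcv_e": self.gcv_e, "d_g": self.d_g, "variant": self.variant,
            "mean_h2": float(self.per_env["h2"].mean()),
            "mean_H2": float(self.per_env["H2"].mean()),
            "mean_sigma2_P": float(self.per_env["sigma2_P"].mean()),
        }
        return out


def residual_var_by_env(residuals, env_labels, npar_per_env) -> dict:
    """Per-environment residual variance of the final residual vector.

    sigma2_ei = sum_j (x_ij - xbar_i)^2 / (n_i - 1 - npar_i), where npar_i
    counts the fixed effects estimated for environment i.
    """
    residuals = np.asarray(residuals, float)
    env_labels = np.asarray(env_labels)
    out = {}
    for env in pd.unique(env_labels):
        x = residuals[env_labels == env]
        npar = int(npar_per_env[env]) if not np.isscalar(npar_per_env) \
            else int(npar_per_env)
        denom = len(x) - 1 - npar
        if denom <= 0:
            raise ValueError(
                f"environment {env!r}: denominator n - 1 - npar = {denom} <= 0")
        out[env] = float(((x - x.mean()) ** 2).sum() / denom)
    return out


def heritability_plot(sigma2_g, sigma2_l, sigma2_f, sigma2_e, d_g=1.0,
                      fold_dg=False):
    """Plot-level phenotypic variance and heritabilities for one environment.

    Default ("reported-scale") treats d(G) as already folded into sigma2_g:
    sigma2_P = sigma2_l + sigma2_g + sigma2_f + sigma2_e and
    h2 = sigma2_g / sigma2_P.  With ``fold_dg=True`` the genomic variance is
    multiplied by d(G) (one plus the genomic inbreeding coefficient) in both
    the numerator and sigma2_P.
    """
    for name, v in (("sigma2_g", sigma2_g), ("sigma2_l", sigma2_l),
                    ("sigma2_f", sigma2_f), ("sigma2_e", sigma2_e)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    g_term = d_g * sigma2_g if fold_dg else sigma2_g
    sigma2_p = sigma2_l + g_term + sigma2_f + sigma2_e
    if sigma2_p <= 0:
        raise ValueError("zero phenotypic variance")
    h2 = g_term / sigma2_p
    big_h2 = (sigma2_l + g_term) / sigma2_p
    return sigma2_p, h2, big_h2


def dispersion_scale_conversion(sigma2_gd, mean_recip_w, sigma2_e_scale=1.0):
    """Exponential-scale dispersion variance to the additive scale.

    sigma2_e_add = mean(1/W) * sigma2_e (the average plot residual variance),
    sigma2_e_exp = sigma2_e_add * exp(0.5 * sigma2_gd),
    sigma2_gd_add = (sigma2_e_exp)^2 * exp(sigma2_gd) - (sigma2_e_add)^2.
    """
    if sigma2_gd < 0 or mean_recip_w < 0 or sigma2_e_scale < 0:
        raise ValueError("inputs must be >= 0")
    sigma2_e_add = mean_recip_w * sigma2_e_scale
    sigma2_e_exp = sigma2_e_add * np.exp(0.5 * sigma2_gd)
    sigma2_gd_add = sigma2_e_exp ** 2 * np.exp(sigma2_gd) - sigma2_e_add ** 2
    if sigma2_gd_add < -1e-12:
        raise ValueError(
            f"negative additive-scale dispersion variance {sigma2_gd_add:g}: "
            "inconsistent inputs")
    return float(sigma2_e_add), float(sigma2_e_exp), float(max(sigma2_gd_add, 0.0))


def mulder_hill_h2(sigma2_gd_add, sigma2_p):
    """Heritability of residual variance:
    h2_d = sigma2_gd_add / (2 sigma4_P + 3 sigma2_gd_add), value in [0, 1/3).
    """
    if sigma2_gd_add < 0 or sigma2_p < 0:
        raise ValueError("inputs must be >= 0")
    denom = 2.0 * sigma2_p ** 2 + 3.0 * sigma2_gd_add
    if denom == 0:
        raise ValueError("h2_d undefined: both inputs zero")
    return float(sigma2_gd_add / denom)


def evolvability(sigma2_gd):
    """GCV_E = sqrt(sigma2_gd): proportional change in residual variance per
    unit selection on dispersion breeding values (log scale)."""
    if sigma2_gd < 0:
        raise ValueError("sigma2_gd must be >= 0")
    return float(np.sqrt(sigma2_gd))


def genetic_correlation(sigma_g_gd, sigma2_g, sigma2_gd):
    """rho_g,gd = sigma_g,gd / sqrt(sigma2_g * sigma2_gd)."""
    if sigma2_g <= 0 or sigma2_gd <= 0:
        raise ValueError("rho_g,gd undefined at zero variance")
    rho = sigma_g_gd / np.sqrt(sigma2_g * sigma2_gd)
    if abs(rho) > 1.0 + 1e-6:
        raise ValueError(f"|rho| = {abs(rho):g} exceeds 1 beyond rounding")
    return float(np.clip(rho, -1.0, 1.0))


def genetic_params_from_fit(fit, d_g: float | None = None,
                            fold_dg: bool = False) -> GeneticParams:
    """All genetic parameters from a converged dispersion-model fit.

    ``fit`` is a DHGLMResults; the per-environment residual variances use the
    final residual vector, mean(1/W) is the unweighted mean of the converged
    fitted dispersion values, and the phenotypic variance entering h2_d is
    the average across environments.
    """
    if d_g is None:
        d_g = fit.model.grm.mean_diagonal()
    sig_e = fit.sigma2_e_by_env()
    rows = []
    for env in fit.env_levels:
        s2p, h2, big = heritability_plot(
            fit.sigma2_g, fit.sigma2_l, fit.sigma2_f, sig_e[env],
            d_g=d_g, fold_dg=fold_dg)
        rows.append((env, sig_e[env], s2p, h2, big))
    per_env = pd.DataFrame(
        rows, columns=["env", "sigma2_e", "sigma2_P", "h2", "H2"])
    mean_recip_w = float(np.mean(1.0 / fit.w_mean))
    e_add, e_exp, gd_add = dispersion_scale_conversion(
        fit.sigma2_gd, mean_recip_w, fit.sigma2_e_scale)
    sigma2_p_avg = float(per_env["sigma2_P"].mean())
    h2d = mulder_hill_h2(gd_add, sigma2_p_avg)
    gcv = evolvability(fit.sigma2_gd)
    if fit.sigma2_g > 0 and fit.sigma2_gd > 0:
        rho = genetic_correlation(fit.sigma_g_gd, fit.sigma2_g, fit.sigma2_gd)
    else:
        rho = float("nan")
    return GeneticParams(
        per_env=per_env, sigma2_g=fit.sigma2_g, sigma2_gd=fit.sigma2_gd,
        sigma_g_gd=fit.sigma_g_gd, rho_g_gd=rho, sigma2_e_add=e_add,
        sigma2_e_exp=e_exp, sigma2_gd_add=gd_add, h2_d=h2d, gcv_e=gcv,
        d_g=d_g, variant="dg-folded" if fold_dg else "reported-scale")
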