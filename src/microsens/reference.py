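"""Published reference values for the winter-wheat grain-yield population.

The bundled table holds the per-environment variance components and
heritabilities reported for the 2,456-line Danish winter-wheat population
(26 year-location environments, yield in kg per 8.25 m2 plot) under the
reference heterogeneous-residual mixed model (``lmm_het``) and the double
hierarchical GLM (``dhglm``).  They serve as a desk-scale consistency
fixture: the package's heritability arithmetic must reproduce the printed
sigma2_P, h2 and H2 from the printed components.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# shared variance components of the wheat population (SDs in parentheses in
# the source report)
COMPONENTS = {
    "lmm_het": {"sigma2_g": 0.054, "sigma2_l": 0.060, "sigma2_f": 0.118},
    "dhglm": {"sigma2_g": 0.054, "sigma2_l": 0.062, "sigma2_f": 0.108,
              "sigma2_gd": 0.004, "h2_d": 0.033, "rho_g_gd": 0.502},
}

#: mean GRM diagonal of the wheat population (1 + genomic inbreeding)
D_G = 1.84
#: SNPs retained by quality control (call rate >= 0.90, MAF >= 0.05)
N_SNPS_QC = 12893
#: average number of plot replicates per line
K_MEAN = 8.91
#: evolvability reported for the population (sqrt of sigma2_gd, log scale)
GCV_E = 0.061
#: genetic correlation after log-transforming the response
RHO_G_GD_LOG = -0.698
#: kg per 8.25 m2 plot -> tonnes per hectare
PLOT_KG_TO_T_HA = 10000.0 / 8.25 / 1000.0


def load_reference_table() -> pd.DataFrame:
    """Per-environment (sigma2_e, sigma2_P, h2, H2) for both models."""
    with resources.files("microsens.data") \
            .joinpath("wheat_reference_components.csv").open() as fh:
        return pd.read_csv(fh)


def reproduce_heritability_rows(model: str = "dhglm") -> pd.DataFrame:
    """Recompute each printed (sigma2_P, h2, H2) row from the printed
    variance components with the reported-scale heritability arithmetic.

    Returns the table with computed columns and absolute deviations after
    rounding the computed values to the printed precision (3 decimals).
    """
    from .genpar import heritability_plot

    tab = load_reference_table()
    tab = tab[tab["model"] == model].copy()
    comp = COMPONENTS[model]
    rows = []
    for _, r in tab.iterrows():
        s2p, h2, big = heritability_plot(
            comp["sigma2_g"], comp["sigma2_l"], comp["sigma2_f"],
            r["sigma2_e"])
        rows.append((round(s2p, 3), round(h2, 3), round(big, 3)))
    tab[["sigma2_P_calc", "h2_calc", "H2_calc"]] = rows
    # all quantities live at printed precision (3 decimals); rounding the
    # deviations keeps 0.002 comparisons free of floating-point dust
    tab["dev_sigma2_P"] = (tab["sigma2_P_calc"] - tab["sigma2_P"]).abs().round(9)
    tab["dev_h2"] = (tab["h2_calc"] - tab["h2"]).abs().round(9)
    tab["dev_H2"] = (tab["H2_calc"] - tab["H2"]).abs().round(9)
    return tab
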