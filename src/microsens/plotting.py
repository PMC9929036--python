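"""Minimal report graphics."""

from __future__ import annotations

import numpy as np


def yield_boxplot(pheno, path=None, response: str = "yield"):
    """Boxplot of the response per year-location environment, with a dashed
    line at the overall mean.  Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    envs = sorted(pheno["env"].unique())
    data = [np.asarray(pheno.loc[pheno["env"] == e, response], float)
            for e in envs]
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(envs)), 4))
    ax.boxplot(data, tick_labels=[f"env#{i + 1}" for i in range(len(envs))],
               showfliers=False)
    ax.axhline(float(np.mean(np.concatenate(data))), ls="--", c="k", lw=1)
    ax.set_ylabel(response)
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
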