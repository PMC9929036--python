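import numpy as np
import pytest

from microsens.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_sim():
    """Small synthetic trial reused across tests: 80 lines, 2 environments,
    4 blocks per trial, no spatial effect, moderate dispersion signal."""
    cfg = SimConfig(n_lines=80, n_snps=600, n_envs=2, blocks_per_trial=4,
                    var_s=0.0, var_gd=0.05, rho=0.5, seed=42)
    pheno, geno, grm, truth = simulate_dataset(cfg)
    pheno = pheno.copy()
    pheno["y_c"] = pheno["yield"]
    return cfg, pheno, geno, grm, truth


@pytest.fixture(scope="session")
def tiny_dhglm(tiny_sim):
    """One converged DHGLM fit on the tiny simulation."""
    from microsens.models import DHGLM

    cfg, pheno, geno, grm, truth = tiny_sim
    return DHGLM(pheno, grm).fit(max_iter=60)


@pytest.fixture(scope="session")
def tiny_lmm(tiny_sim):
    from microsens.models import LMMHet

    cfg, pheno, geno, grm, truth = tiny_sim
    return LMMHet(pheno, grm).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
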