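"""Synthetic multi-environment wheat trial generator with known truth.

The generator emulates the structure of a commercial winter-wheat breeding
programme: nearly homozygous inbred (F6-type) lines genotyped on a SNP panel,
trials laid out as blocks of plots within year-location environments, two
replicates of each line plus repeated check varieties per block, and
plot-level grain yield whose residual variance is exp-linear in a
line-specific dispersion breeding value (the "exponential model"):

    y = trial + g(line) + l(line) + f(line, env) + sum_{3x3} s(plot) + e,
    e ~ N(0, exp(ln sigma2_E + b_d(trial) + g_d(line))),

with (g, g_d) drawn from a bivariate normal with trait covariance
[[var_g, rho*sqrt(var_g*var_gd)], [., var_gd]] Kronecker the genomic
relationship matrix.  Every latent component is recorded in a
:class:`SimTruth` so that estimation code can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomics import GRM, GenotypeMatrix

_LOCATIONS = ("Skive", "Odder", "Holeby")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic trial generator.

    Variance defaults mirror the wheat population the package targets
    (plot-level grain yield in kg per 8.25 m2 plot): additive genetic
    variance ``var_g`` = 0.054, uncorrelated line variance ``var_l`` = 0.062,
    line-by-environment variance ``var_f`` = 0.108, baseline residual
    variance exp(``base_log_resid_var``) ~ 0.085, dispersion genetic variance
    ``var_gd`` on the log scale, genetic correlation ``rho`` between the mean
    and dispersion breeding values, and expected residual heterozygosity
    0.031 for F6 lines.
    """

    n_lines: int = 300
    n_snps: int = 2000
    n_envs: int = 4
    trials_per_env: int = 1
    blocks_per_trial: int = 15
    lines_per_block: int = 21
    reps_per_block: int = 2
    checks_per_block: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    residual_het_rate: float = 0.031
    missing_rate: float = 0.03
    family_size: int = 5
    var_g: float = 0.054
    var_gd: float = 0.004
    rho: float = 0.5
    var_l: float = 0.062
    var_f: float = 0.108
    var_s: float = 0.05
    base_log_resid_var: float = float(np.log(0.085))
    trial_disp_effects: tuple[float, ...] | None = None
    sd_trial_disp: float = 0.0
    mean_yield: float = 9.15
    sd_trial: float = 0.8
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name in ("var_g", "var_gd", "var_l", "var_f", "var_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if abs(self.rho) > 1:
            raise ConfigurationError("|rho| must be <= 1")
        if not (0.0 <= self.residual_het_rate <= 1.0):
            raise ConfigurationError("residual_het_rate must be a proportion")
        if self.n_lines < self.lines_per_block:
            raise ConfigurationError("need at least lines_per_block lines")

    @property
    def plots_per_block(self) -> int:
        return self.reps_per_block * (self.lines_per_block + self.checks_per_block)

    @property
    def n_trials(self) -> int:
        return self.n_envs * self.trials_per_env

    @property
    def n_checks(self) -> int:
        return self.checks_per_block

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """Desk-scale profile: 300 lines, 2,000 SNPs, 4 environments."""
        return cls(**overrides)

    @classmethod
    def paper_scale(cls, **overrides) -> "SimConfig":
        """Profile mirroring the full wheat study dimensions (~2,456 lines,
        ~12,893 SNPs, 26 year-location environments).  Hours-scale to fit."""
        params = dict(n_lines=2456, n_snps=12893, n_envs=26, trials_per_env=1,
                      blocks_per_trial=15)
        params.update(overrides)
        return cls(**params)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset (for recovery tests)."""

    config: SimConfig
    line_ids: np.ndarray
    g: np.ndarray
    g_d: np.ndarray
    l: np.ndarray
    f: pd.DataFrame          # index line, columns env key
    s: np.ndarray            # per plot, aligned with the phenotype table
    trial_effects: dict
    trial_disp_effects: dict
    resid_var: np.ndarray    # realized per-plot residual variance

    def as_dict(self) -> dict:
        return {
            "line_ids": list(self.line_ids),
            "g": self.g.tolist(),
            "g_d": self.g_d.tolist(),
            "l": self.l.tolist(),
            "trial_effects": {k: float(v) for k, v in self.trial_effects.items()},
            "trial_disp_effects": {k: float(v) for k, v in self.trial_disp_effects.items()},
        }


def simulate_genotypes(
    n_lines: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    residual_het_rate: float = 0.031,
    seed: int = 0,
    missing_rate: float = 0.0,
    line_ids=None,
    family_size: int = 5,
) -> GenotypeMatrix:
    """Simulate unlinked SNP genotypes for nearly homozygous inbred lines.

    Each SNP draws a true allele frequency uniformly within ``maf_range``.
    Lines are organised into full-sib families of ``family_size`` derived
    from biparental crosses of homozygous founders, mirroring a breeding
    programme in which each cross yields a handful of selfed sibling lines:
    a line inherits either parental allele with probability 1/2 per SNP
    (loci unlinked) and is heterozygous with probability
    ``residual_het_rate``.  ``family_size=1`` gives unrelated lines.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    if n_lines < 1 or n_snps < 1:
        raise ConfigurationError("n_lines and n_snps must be >= 1")
    if family_size < 1:
        raise ConfigurationError("family_size must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    calls = np.empty((n_lines, n_snps))
    for start in range(0, n_lines, family_size):
        stop = min(start + family_size, n_lines)
        k = stop - start
        # homozygous founder pair; offspring pick a parental allele per SNP
        parents = np.where(rng.random((2, n_snps)) < p[None, :], 1.0, -1.0)
        pick = (rng.random((k, n_snps)) < 0.5).astype(int)
        calls[start:stop] = np.where(pick == 0, parents[0], parents[1])
    het = rng.random((n_lines, n_snps)) < residual_het_rate
    calls[het] = 0.0
    missing = np.zeros_like(het)
    if missing_rate > 0:
        missing = rng.random((n_lines, n_snps)) < missing_rate
    if line_ids is None:
        line_ids = np.array([f"L{i + 1:04d}" for i in range(n_lines)], dtype=object)
    snp_ids = np.array([f"SNP{j + 1:05d}" for j in range(n_snps)], dtype=object)
    return GenotypeMatrix(line_ids=line_ids, snp_ids=snp_ids, calls=calls,
                          missing=missing)


def simulate_genetic_effects(
    G: GRM | np.ndarray,
    var_g: float,
    var_gd: float,
    rho: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw correlated mean/dispersion breeding values (g, g_d).

    (g, g_d) ~ N(0, T kron G) with trait covariance
    T = [[var_g, rho*sqrt(var_g*var_gd)], [., var_gd]].
    """
    if var_g < 0 or var_gd < 0:
        raise ConfigurationError("variances must be >= 0")
    if abs(rho) > 1:
        raise ConfigurationError("|rho| must be <= 1")
    if not isinstance(G, GRM):
        gmat = np.asarray(G, dtype=float)
        G = GRM(line_ids=np.arange(gmat.shape[0]).astype(object),
                values=gmat, denominator=np.nan, n_snps=0)
    L = G.cholesky()
    n = G.n_lines
    # trait-covariance Cholesky, robust at zero variances / |rho| = 1
    c = rho * np.sqrt(var_g * var_gd)
    a11 = np.sqrt(var_g)
    a21 = c / a11 if a11 > 0 else 0.0
    a22 = np.sqrt(max(var_gd - a21 ** 2, 0.0))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    u = L @ z
    g = a11 * u[:, 0]
    g_d = a21 * u[:, 0] + a22 * u[:, 1]
    return g, g_d


def _block_line_assignment(rng, n_lines: int, n_blocks: int, lines_per_block: int):
    """Assign lines to blocks: concatenated random permutations sliced into
    blocks, with within-block duplicates repaired by forward swaps so that the
    multiset of per-line counts is independent of the seed."""
    slots_needed = n_blocks * lines_per_block
    perms = []
    while sum(len(p) for p in perms) < slots_needed:
        perms.append(rng.permutation(n_lines))
    slots = np.concatenate(perms)[:slots_needed].copy()
    for b in range(n_blocks):
        start, stop = b * lines_per_block, (b + 1) * lines_per_block
        seen: set[int] = set()
        for i in range(start, stop):
            if slots[i] in seen:
                for j in range(stop, slots_needed):
                    if slots[j] not in seen:
                        slots[i], slots[j] = slots[j], slots[i]
                        break
            seen.add(slots[i])
        # duplicates can only arise across permutation boundaries, so a swap
        # candidate always exists when n_lines >= lines_per_block
    return slots.reshape(n_blocks, lines_per_block)


def _env_keys(n_envs: int) -> list[str]:
    return [f"{2013 + i // len(_LOCATIONS)}_{_LOCATIONS[i % len(_LOCATIONS)]}"
            for i in range(n_envs)]


def simulate_layout(config: SimConfig) -> pd.DataFrame:
    """Field-trial skeleton: one row per plot, no yield yet.

    Within each trial, blocks are columns of the plot grid (x = block index,
    y = position within block).  Each block holds ``reps_per_block`` copies of
    each of its ``lines_per_block`` lines plus ``reps_per_block`` copies of
    each check, in seed-randomized positions.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    line_ids = [f"L{i + 1:04d}" for i in range(cfg.n_lines)]
    check_ids = [f"CHK{i + 1}" for i in range(cfg.n_checks)]
    rows = []
    env_keys = _env_keys(cfg.n_envs)
    for ei, env in enumerate(env_keys):
        year, loc = env.split("_")
        for t in range(cfg.trials_per_env):
            trial = f"{env}_T{t + 1}"
            assign = _block_line_assignment(
                rng, cfg.n_lines, cfg.blocks_per_trial, cfg.lines_per_block)
            for b in range(cfg.blocks_per_trial):
                entries = []
                for li in assign[b]:
                    entries += [(line_ids[li], False)] * cfg.reps_per_block
                for ck in check_ids:
                    entries += [(ck, True)] * cfg.reps_per_block
                order = rng.permutation(len(entries))
                for pos, k in enumerate(order):
                    lid, is_check = entries[k]
                    rows.append((lid, year, loc, trial, b + 1, b + 1, pos + 1,
                                 is_check, env))
    pheno = pd.DataFrame(
        rows, columns=["line", "year", "location", "trial", "block", "x", "y",
                       "is_check", "env"])
    return pheno


def neighborhood_incidence(pheno: pd.DataFrame):
    """Sparse incidence of the 3x3 plot neighborhood within trial.

    Row n has a 1 for the target plot and each of its existing (<= 8)
    neighbors on the trial grid; the spatial contribution to a plot is the
    sum of the iid plot effects over that neighborhood.
    """
    from scipy import sparse

    n = len(pheno)
    key = {}
    for idx, (trial, x, y) in enumerate(zip(pheno["trial"], pheno["x"], pheno["y"])):
        k = (trial, int(x), int(y))
        if k in key:
            raise ValueError(f"duplicate plot coordinate {k}")
        key[k] = idx
    rows, cols = [], []
    for idx, (trial, x, y) in enumerate(zip(pheno["trial"], pheno["x"], pheno["y"])):
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                j = key.get((trial, int(x) + dx, int(y) + dy))
                if j is not None:
                    rows.append(idx)
                    cols.append(j)
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def simulate_truth(config: SimConfig, grm: GRM, pheno: pd.DataFrame) -> SimTruth:
    """Draw every latent component of the generative model."""
    cfg = config
    line_ids = np.asarray(grm.line_ids, dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    g, g_d = simulate_genetic_effects(
        grm, cfg.var_g, cfg.var_gd, cfg.rho,
        seed=np.random.SeedSequence([cfg.seed, 3]))
    l = rng.normal(0.0, np.sqrt(cfg.var_l), size=len(line_ids))
    env_keys = _env_keys(cfg.n_envs)
    f = pd.DataFrame(
        rng.normal(0.0, np.sqrt(cfg.var_f), size=(len(line_ids), cfg.n_envs)),
        index=line_ids, columns=env_keys)
    s = rng.normal(0.0, np.sqrt(cfg.var_s), size=len(pheno))
    trials = list(dict.fromkeys(pheno["trial"]))
    trial_effects = {t: cfg.mean_yield + rng.normal(0.0, cfg.sd_trial)
                     for t in trials}
    if cfg.trial_disp_effects is not None:
        if len(cfg.trial_disp_effects) != len(trials):
            raise ConfigurationError(
                f"trial_disp_effects has {len(cfg.trial_disp_effects)} entries "
                f"for {len(trials)} trials")
        trial_disp = {t: float(v) for t, v in zip(trials, cfg.trial_disp_effects)}
    else:
        trial_disp = {t: rng.normal(0.0, cfg.sd_trial_disp) if cfg.sd_trial_disp > 0
                      else 0.0 for t in trials}
    line_pos = {lid: i for i, lid in enumerate(line_ids)}
    idx = np.array([line_pos[lid] for lid in pheno["line"]])
    log_var = (cfg.base_log_resid_var
               + np.array([trial_disp[t] for t in pheno["trial"]])
               + g_d[idx])
    return SimTruth(config=cfg, line_ids=line_ids, g=g, g_d=g_d, l=l, f=f, s=s,
                    trial_effects=trial_effects, trial_disp_effects=trial_disp,
                    resid_var=np.exp(log_var))


def simulate_phenotypes(
    skeleton: pd.DataFrame, truth: SimTruth, seed: int | None = None
) -> pd.DataFrame:
    """Fill the yield column of a layout skeleton from a SimTruth."""
    cfg = truth.config
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    line_pos = {lid: i for i, lid in enumerate(truth.line_ids)}
    try:
        idx = np.array([line_pos[lid] for lid in skeleton["line"]])
    except KeyError as exc:  # pragma: no cover - guarded by construction
        raise ConfigurationError(f"line {exc} missing from truth") from exc
    y = np.array([truth.trial_effects[t] for t in skeleton["trial"]])
    y = y + truth.g[idx] + truth.l[idx]
    y = y + np.array([truth.f.at[lid, env]
                      for lid, env in zip(skeleton["line"], skeleton["env"])])
    if cfg.var_s > 0:
        z_nbr = neighborhood_incidence(skeleton)
        y = y + z_nbr @ truth.s
    e = rng.standard_normal(len(skeleton)) * np.sqrt(truth.resid_var)
    pheno = skeleton.copy()
    pheno["yield"] = y + e
    return pheno


def simulate_dataset(config: SimConfig):
    """Full synthetic dataset: (phenotypes, genotypes, GRM, truth).

    Checks are simulated as ordinary genotyped lines flagged ``is_check`` and
    are included in the genotype panel and GRM.
    """
    from .genomics import build_grm

    cfg = config
    all_ids = np.array(
        [f"L{i + 1:04d}" for i in range(cfg.n_lines)]
        + [f"CHK{i + 1}" for i in range(cfg.n_checks)], dtype=object)
    geno = simulate_genotypes(
        n_lines=len(all_ids), n_snps=cfg.n_snps, maf_range=cfg.maf_range,
        residual_het_rate=cfg.residual_het_rate,
        seed=np.random.SeedSequence([cfg.seed, 0]),
        missing_rate=cfg.missing_rate, line_ids=all_ids,
        family_size=cfg.family_size)
    grm = build_grm(geno)
    skeleton = simulate_layout(cfg)
    truth = simulate_truth(cfg, grm, skeleton)
    pheno = simulate_phenotypes(skeleton, truth)
    return pheno, geno, grm, truth
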