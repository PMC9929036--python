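"""File formats, run configuration, and the end-to-end pipeline runner.

Phenotypes travel as CSV/TSV with columns line, year, location, trial,
block, x, y, yield; genotypes as line x SNP CSV (codes -1/0/1, missing
empty or NA) or PLINK-style .raw (0/1/2 recoded internally).  The GRM is
written as a square CSV with line ids, with a compact binary (.npz)
variant.  ``run_pipeline`` chains QC -> GRM -> spatial correction ->
LMM-HET -> DHGLM -> genetic parameters -> cross-validation and writes a
manifest recording versions, seeds, parameters and per-stage checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GRM, GenotypeMatrix

log = logging.getLogger("microsens")

PHENO_COLUMNS = ("line", "year", "location", "trial", "block", "x", "y", "yield")


class SchemaError(ValueError):
    pass


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    """Typed plot table with a derived year-location environment key."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    tab = pd.read_csv(path, sep=sep)
    missing = [c for c in PHENO_COLUMNS if c not in tab.columns]
    if missing:
        raise SchemaError(f"phenotype file lacks column(s) {missing}")
    bad = pd.to_numeric(tab["yield"], errors="coerce").isna() & tab["yield"].notna()
    if bad.any():
        raise SchemaError(
            f"non-numeric yield in rows {list(tab.index[bad][:5])}")
    tab["yield"] = pd.to_numeric(tab["yield"])
    tab["env"] = tab["year"].astype(str) + "_" + tab["location"].astype(str)
    dup = tab.duplicated(subset=["env", "trial", "x", "y"])
    if dup.any():
        raise SchemaError(
            "duplicated plot coordinates: "
            f"{tab.loc[dup, ['trial', 'x', 'y']].head().to_dict('records')}")
    if "is_check" in tab.columns:
        tab["is_check"] = tab["is_check"].astype(bool)
    return tab


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    cols = [c for c in pheno.columns if c != "env"]
    pheno[cols].to_csv(path, index=False)


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def read_genotypes(path, dialect: str = "csv") -> GenotypeMatrix:
    """Genotype matrix from CSV (-1/0/1) or PLINK .raw (0/1/2 -> x-1)."""
    path = Path(path)
    if dialect == "csv":
        tab = pd.read_csv(path, index_col=0)
        calls = tab.to_numpy(dtype=float)
        valid = np.isnan(calls) | np.isin(calls, (-1.0, 0.0, 1.0))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise SchemaError(
                f"unknown genotype code {calls[i, j]!r} at line "
                f"{tab.index[i]!r}, SNP {tab.columns[j]!r}")
        return GenotypeMatrix(line_ids=tab.index.to_numpy(dtype=object),
                              snp_ids=tab.columns.to_numpy(dtype=object),
                              calls=np.nan_to_num(calls),
                              missing=np.isnan(calls))
    if dialect == "plink_raw":
        tab = pd.read_csv(path, sep=r"\s+")
        meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
                if c in tab.columns]
        if "IID" not in tab.columns:
            raise SchemaError(".raw file lacks IID column")
        snp_cols = [c for c in tab.columns if c not in meta]
        calls = tab[snp_cols].apply(pd.to_numeric, errors="coerce") \
                             .to_numpy(dtype=float)
        valid = np.isnan(calls) | np.isin(calls, (0.0, 1.0, 2.0))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise SchemaError(
                f"unknown dosage {calls[i, j]!r} at line "
                f"{tab['IID'].iloc[i]!r}, SNP {snp_cols[j]!r}")
        return GenotypeMatrix(line_ids=tab["IID"].to_numpy(dtype=object),
                              snp_ids=np.array(snp_cols, dtype=object),
                              calls=np.nan_to_num(calls - 1.0),
                              missing=np.isnan(calls))
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    calls = geno.calls.astype(object)
    calls[geno.missing] = np.nan
    pd.DataFrame(calls, index=geno.line_ids, columns=geno.snp_ids) \
        .to_csv(path, index_label="line")


def write_genotypes_raw(geno: GenotypeMatrix, path) -> None:
    """PLINK-style .raw: dosages 0/1/2 (internal code + 1), NA for missing."""
    dosage = (geno.calls + 1.0).astype(object)
    dosage[geno.missing] = "NA"
    tab = pd.DataFrame(dosage, columns=geno.snp_ids)
    meta = pd.DataFrame({"FID": geno.line_ids, "IID": geno.line_ids,
                         "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9})
    pd.concat([meta.reset_index(drop=True), tab.reset_index(drop=True)],
              axis=1).to_csv(path, sep=" ", index=False)


# ----------------------------------------------------------------------
# GRM
# ----------------------------------------------------------------------

def write_grm(grm: GRM, path, binary: bool = False) -> None:
    path = Path(path)
    if binary:
        np.savez_compressed(path, line_ids=np.asarray(grm.line_ids, dtype=str),
                            values=grm.values,
                            denominator=grm.denominator, n_snps=grm.n_snps)
    else:
        pd.DataFrame(grm.values, index=grm.line_ids, columns=grm.line_ids) \
            .to_csv(path, index_label="line")


def read_grm(path) -> GRM:
    path = Path(path)
    if path.suffix == ".npz":
        dat = np.load(path, allow_pickle=False)
        return GRM(line_ids=dat["line_ids"].astype(object),
                   values=dat["values"],
                   denominator=float(dat["denominator"]),
                   n_snps=int(dat["n_snps"]))
    tab = pd.read_csv(path, index_col=0)
    return GRM(line_ids=tab.index.to_numpy(dtype=object),
               values=tab.to_numpy(dtype=float),
               denominator=float("nan"), n_snps=0)


# ----------------------------------------------------------------------
# configuration and pipeline
# ----------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run needs, serialisable to JSON."""

    phenotypes: str
    genotypes: str
    out_dir: str
    genotype_dialect: str = "csv"
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    run_spatial: bool = True
    run_lmm: bool = True
    run_dhglm: bool = True
    run_genpar: bool = True
    run_cv: bool = False
    dhglm_tol: float = 1e-5
    dhglm_max_iter: int = 100
    bootstrap_B: int = 10000
    seed: int = 0

    def validate(self):
        for p in (self.phenotypes, self.genotypes):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return self

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.as_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and return the output manifest."""
    from . import __version__
    from .genomics import build_grm, snp_qc
    from .genpar import genetic_params_from_fit
    from .models import DHGLM, LMMHet, fit_spatial_stage

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    manifest: dict = {"version": __version__, "config": config.as_dict(),
                      "config_hash": chash, "stages": {}, "checksums": {}}

    def record(stage: str, path: Path | None = None, **info):
        manifest["stages"][stage] = {"status": "done", **info}
        if path is not None:
            manifest["checksums"][path.name] = _sha256(path)
        log.info("stage %s done", stage)

    stage = "read"
    try:
        pheno = read_phenotypes(config.phenotypes)
        geno = read_genotypes(config.genotypes, config.genotype_dialect)
        record("read", n_plots=len(pheno), n_lines=geno.n_lines,
               n_snps=geno.n_snps)

        stage = "qc"
        geno_qc, qc_report = snp_qc(geno, config.call_rate_min, config.maf_min)
        record("qc", **qc_report.as_dict())

        stage = "grm"
        grm = build_grm(geno_qc)
        grm_path = out / "grm.csv"
        write_grm(grm, grm_path)
        record("grm", grm_path, d_g=grm.mean_diagonal(), jitter=grm.jitter)

        stage = "spatial"
        if config.run_spatial:
            corrected = fit_spatial_stage(pheno, grm)
            cp = out / "corrected_phenotypes.csv"
            corrected.pheno.drop(columns=["env"]).to_csv(cp, index=False)
            record("spatial", cp, sigma2_s=corrected.sigma2_s)
        else:
            pheno = pheno.copy()
            pheno["y_c"] = pheno["yield"]
            corrected = pheno
            manifest["stages"]["spatial"] = {"status": "skipped"}

        lmm_res = None
        stage = "lmm_het"
        if config.run_lmm:
            lmm_res = LMMHet(corrected, grm).fit()
            lp = out / "lmm_het_fit.json"
            lp.write_text(json.dumps({
                "vc": lmm_res.vc.as_dict(),
                "loglik": lmm_res.vc.loglik,
                "n_iter": lmm_res.vc.n_iter,
                "trace": lmm_res.vc.trace}, indent=1))
            record("lmm_het", lp, **lmm_res.vc.as_dict())
        else:
            manifest["stages"]["lmm_het"] = {"status": "skipped"}

        dh_res = None
        stage = "dhglm"
        if config.run_dhglm:
            dh_res = DHGLM(corrected, grm).fit(tol=config.dhglm_tol,
                                               max_iter=config.dhglm_max_iter)
            dp = out / "dhglm_fit.json"
            dp.write_text(json.dumps({
                "vc": dh_res.vc.as_dict(),
                "n_outer": dh_res.n_outer,
                "rho_g_gd": dh_res.rho_g_gd,
                "outer_trace": dh_res.outer_trace}, indent=1))
            blup = pd.DataFrame({"line": dh_res.line_ids,
                                 "g_hat": dh_res.g_hat,
                                 "gd_hat": dh_res.gd_hat})
            bp = out / "dhglm_blups.csv"
            blup.to_csv(bp, index=False)
            record("dhglm", dp, n_outer=dh_res.n_outer)
        else:
            manifest["stages"]["dhglm"] = {"status": "skipped"}

        stage = "genpar"
        if config.run_genpar and dh_res is not None:
            params = genetic_params_from_fit(dh_res)
            gp = out / "genetic_params.json"
            gp.write_text(json.dumps(params.as_dict(), indent=1))
            record("genpar", gp, h2_d=params.h2_d, gcv_e=params.gcv_e)
        else:
            manifest["stages"]["genpar"] = {"status": "skipped"}

        stage = "cv"
        if config.run_cv:
            from .crossval import evaluate_model
            reports = {}
            if lmm_res is not None:
                reports["lmm_het"] = evaluate_model(
                    lmm_res, "lmm_het", B=config.bootstrap_B,
                    seed=config.seed).as_dict()
            if dh_res is not None:
                reports["dhglm"] = evaluate_model(
                    dh_res, "dhglm", B=config.bootstrap_B,
                    seed=config.seed).as_dict()
            cvp = out / "cv_report.json"
            cvp.write_text(json.dumps(reports, indent=1))
            record("cv", cvp)
        else:
            manifest["stages"]["cv"] = {"status": "skipped"}
    except Exception as exc:
        manifest["stages"][stage] = {"status": "error", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
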