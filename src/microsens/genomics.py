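"""SNP quality control and genomic relationship matrix (GRM) construction.

Genotypes are held line x SNP, coded -1/0/1 (homozygote / heterozygote /
alternate homozygote) with an explicit missing mask.  The GRM follows
VanRaden's first method: G = QQ' / (2 * sum_j p_j (1 - p_j)), where Q is the
genotype matrix centered by column on 2(p_j - 0.5) and missing entries are
imputed with the (centered) column mean, i.e. set to zero after centering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EmptyPanelError(ValueError):
    """All SNPs were removed by quality control."""


@dataclass
class GenotypeMatrix:
    """Line x SNP genotype calls coded -1/0/1 with a missing mask.

    Parameters
    ----------
    line_ids : array of str
        Identifiers of the genotyped lines (rows).
    snp_ids : array of str
        SNP identifiers (columns).
    calls : ndarray, shape (n_lines, n_snps)
        Genotype codes in {-1, 0, 1}; entries under ``missing`` are ignored.
    missing : ndarray of bool, same shape
        True where the call is missing.
    """

    line_ids: np.ndarray
    snp_ids: np.ndarray
    calls: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.missing is None:
            self.missing = np.isnan(self.calls)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.calls.shape != self.missing.shape:
            raise ValueError("calls and missing mask shapes differ")
        if self.calls.shape != (len(self.line_ids), len(self.snp_ids)):
            raise ValueError("calls shape inconsistent with id vectors")
        observed = self.calls[~self.missing]
        if observed.size and not np.isin(observed, (-1.0, 0.0, 1.0)).all():
            bad = observed[~np.isin(observed, (-1.0, 0.0, 1.0))]
            raise ValueError(f"genotype codes outside {{-1,0,1}}: {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the +1 allele over non-missing calls.

        With -1/0/1 coding the allele dosage is (call + 1) / 2.
        """
        calls = np.where(self.missing, np.nan, self.calls)
        with np.errstate(invalid="ignore"):
            p = np.nanmean((calls + 1.0) / 2.0, axis=0)
        return p

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls across lines."""
        return 1.0 - self.missing.mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def heterozygosity(self) -> float:
        """Overall fraction of heterozygous (0) calls among non-missing ones."""
        obs = self.calls[~self.missing]
        return float((obs == 0).mean()) if obs.size else float("nan")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_low_call_rate: int
    n_low_maf: int
    call_rate_min: float
    maf_min: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its scaling metadata."""

    line_ids: np.ndarray
    values: np.ndarray
    denominator: float
    n_snps: int
    jitter: float = 0.0
    _chol: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _inv: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape inconsistent with line ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def mean_diagonal(self) -> float:
        """d(G): mean diagonal, one plus the genomic inbreeding coefficient."""
        return float(np.diag(self.values).mean())

    def cholesky(self, jitter_step: float = 1e-8, max_tries: int = 10) -> np.ndarray:
        """Lower Cholesky factor, adding diagonal jitter only if needed.

        A GRM built with in-sample allele frequencies is exactly singular
        (its rows sum to zero), and a floating-point Cholesky of a singular
        matrix can "succeed" with a near-zero pivot, poisoning every inverse
        built from it.  A factorization is therefore only accepted when its
        smallest squared pivot clears a relative threshold; otherwise the
        diagonal jitter escalates by decades from ``jitter_step``.
        """
        if self._chol is not None:
            return self._chol
        pivot_floor = 1e-7 * float(np.diag(self.values).mean())
        jitter = 0.0
        mat = self.values
        for _ in range(max_tries):
            try:
                chol = np.linalg.cholesky(mat)
                if float(np.diag(chol).min()) ** 2 >= pivot_floor:
                    self._chol = chol
                    self.jitter = jitter
                    if jitter > 0.0:
                        import logging
                        logging.getLogger(__name__).info(
                            "GRM rank deficient; diagonal jitter %g applied", jitter)
                    return self._chol
            except np.linalg.LinAlgError:
                pass
            jitter = jitter_step if jitter == 0.0 else jitter * 10.0
            mat = self.values + jitter * np.eye(self.n_lines)
        raise np.linalg.LinAlgError(
            "GRM not positive definite even with jitter "
            f"{jitter:g}; min eigenvalue {np.linalg.eigvalsh(self.values).min():g}"
        )

    def inverse(self) -> np.ndarray:
        if self._inv is None:
            L = self.cholesky()
            eye = np.eye(self.n_lines)
            Linv = np.linalg.solve(L, eye)
            self._inv = Linv.T @ Linv
        return self._inv

    def logdet(self) -> float:
        L = self.cholesky()
        return 2.0 * float(np.log(np.diag(L)).sum())


def snp_qc(
    m_raw: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs on call rate and minor allele frequency.

    A SNP is retained when call rate >= ``call_rate_min`` AND
    MAF >= ``maf_min`` (the boundary is kept; only strictly lower values are
    removed).
    """
    if m_raw.n_snps == 0:
        raise EmptyPanelError("input panel has no SNPs")
    cr = m_raw.call_rate()
    maf = m_raw.maf()
    low_cr = cr < call_rate_min
    low_maf = ~np.isfinite(maf) | (maf < maf_min)
    keep = ~(low_cr | low_maf)
    report = QCReport(
        n_input=m_raw.n_snps,
        n_retained=int(keep.sum()),
        n_low_call_rate=int(low_cr.sum()),
        n_low_maf=int(low_maf.sum()),
        call_rate_min=call_rate_min,
        maf_min=maf_min,
    )
    if report.n_retained == 0:
        raise EmptyPanelError(
            f"quality control removed all {m_raw.n_snps} SNPs "
            f"(call rate < {call_rate_min}: {report.n_low_call_rate}, "
            f"MAF < {maf_min}: {report.n_low_maf})"
        )
    filtered = GenotypeMatrix(
        line_ids=m_raw.line_ids,
        snp_ids=m_raw.snp_ids[keep],
        calls=m_raw.calls[:, keep],
        missing=m_raw.missing[:, keep],
    )
    return filtered, report


def center_impute(m: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Center genotype columns on 2(p_j - 0.5) and zero-impute missing calls.

    Returns
    -------
    Q : ndarray
        Centered matrix M - P with missing entries set to 0 (the centered
        column mean).
    p : ndarray
        Allele frequencies used for centering (from non-missing calls).
    """
    p = m.allele_freq()
    if np.isnan(p).any():
        bad = m.snp_ids[np.isnan(p)]
        raise ValueError(f"SNPs with no non-missing calls: {list(bad[:5])}")
    q = m.calls - 2.0 * (p - 0.5)
    q[m.missing] = 0.0
    return q, p


def grm_vanraden1(q: np.ndarray, p: np.ndarray, line_ids=None) -> GRM:
    """VanRaden method-1 GRM: G = QQ' / (2 sum_j p_j(1-p_j))."""
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    denom = 2.0 * float((p * (1.0 - p)).sum())
    if denom <= 0.0:
        raise ValueError("zero scaling denominator: all SNPs monomorphic")
    g = (q @ q.T) / denom
    g = 0.5 * (g + g.T)
    if line_ids is None:
        line_ids = np.array([f"L{i}" for i in range(q.shape[0])], dtype=object)
    return GRM(line_ids=line_ids, values=g, denominator=denom, n_snps=q.shape[1])


def build_grm(m: GenotypeMatrix) -> GRM:
    """QC'd genotypes -> centered/imputed -> VanRaden method-1 GRM."""
    q, p = center_impute(m)
    return grm_vanraden1(q, p, line_ids=m.line_ids)
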