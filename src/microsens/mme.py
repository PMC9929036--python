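"""Henderson mixed-model equations with diagonal-block absorption.

The estimation engine assembles, for fixed parameter values, the coefficient
matrix of the mixed-model equations (MME)

    C = [X Z]' R^{-1} [X Z] + blockdiag(0, G_1^{-1}, ..., G_k^{-1}),

factors it, and exposes solves, the REML log-determinant, hat-matrix
leverages, and arbitrary entries of C^{-1}.  One random term whose incidence
has a single nonzero per row and identity covariance (typically the
line-by-environment interaction, the largest block) is absorbed: its C-block
is diagonal, so the remaining "core" system is the dense Schur complement

    S = C_cc - C_cf diag(C_ff)^{-1} C_fc,

which stays small (fixed effects + genomic + line effects) even when the
absorbed block is large.  All C^{-1} quantities are recovered from S^{-1} and
the absorption by standard block-inverse identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from .genomics import GRM


@dataclass
class RandomTerm:
    """One random effect: incidence + covariance structure.

    kind is one of
      - "iid": u ~ N(0, I sigma2), one free variance,
      - "grm": u ~ N(0, G sigma2), GRM-correlated, one free variance,
      - "grm_bivariate": u = (u1, u2) stacked trait-major, 2n levels,
        cov = T kron G with T = [[t11, t12], [t12, t22]] unstructured
        (three free parameters t11, t12, t22).
    """

    name: str
    Z: sparse.csr_matrix
    kind: str = "iid"
    grm: GRM | None = None

    def __post_init__(self):
        self.Z = sparse.csr_matrix(self.Z)
        if self.kind not in ("iid", "grm", "grm_bivariate"):
            raise ValueError(f"unknown random-term kind {self.kind!r}")
        if self.kind in ("grm", "grm_bivariate") and self.grm is None:
            raise ValueError(f"term {self.name!r} needs a GRM")
        if self.kind == "grm_bivariate" and self.Z.shape[1] != 2 * self.grm.n_lines:
            raise ValueError("bivariate term incidence must have 2*n_lines columns")
        if self.kind == "grm" and self.Z.shape[1] != self.grm.n_lines:
            raise ValueError("grm term incidence must have n_lines columns")

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def n_params(self) -> int:
        return 3 if self.kind == "grm_bivariate" else 1

    @property
    def param_names(self) -> list[str]:
        if self.kind == "grm_bivariate":
            return [f"{self.name}:var1", f"{self.name}:cov12", f"{self.name}:var2"]
        return [f"{self.name}:var"]

    def absorbable(self) -> bool:
        """True when the term's MME diagonal block is diagonal."""
        if self.kind != "iid":
            return False
        nnz_per_row = np.diff(self.Z.indptr)
        return bool((nnz_per_row <= 1).all())


@dataclass
class ResidualClass:
    """Observations sharing one residual scale: R_nn = sigma2 / w_n.

    ``weights`` w are known (all one for a plain homoscedastic class); the
    free parameter is the scale sigma2.
    """

    name: str
    index: np.ndarray              # integer obs indices
    weights: np.ndarray = None     # type: ignore[assignment]

    def __post_init__(self):
        self.index = np.asarray(self.index, dtype=int)
        if self.weights is None:
            self.weights = np.ones(len(self.index))
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise ValueError(f"residual class {self.name!r} has non-positive weights")


def bivariate_trait_cov(t11: float, t12: float, t22: float) -> np.ndarray:
    return np.array([[t11, t12], [t12, t22]])


class MMESystem:
    """The assembled, factored MME at one parameter value."""

    def __init__(self, X: np.ndarray, terms: list[RandomTerm],
                 classes: list[ResidualClass], y: np.ndarray,
                 theta: np.ndarray, param_names: list[str],
                 absorb: str | None = "auto"):
        self.X = np.asarray(X, dtype=float)
        self.terms = terms
        self.classes = classes
        self.y = np.asarray(y, dtype=float)
        self.theta = np.asarray(theta, dtype=float)
        self.param_names = list(param_names)
        n = len(self.y)
        self.n_obs = n
        self.p = self.X.shape[1]

        # --- parameter bookkeeping -------------------------------------
        self.term_param_slices: list[slice] = []
        off = 0
        for t in terms:
            self.term_param_slices.append(slice(off, off + t.n_params))
            off += t.n_params
        self.class_param_index = list(range(off, off + len(classes)))
        if off + len(classes) != len(theta):
            raise ValueError("theta length inconsistent with model")

        # --- residual vector -------------------------------------------
        rinv = np.empty(n)
        rinv.fill(np.nan)
        self.class_sigma2 = self.theta[self.class_param_index]
        for c, s2 in zip(classes, self.class_sigma2):
            rinv[c.index] = c.weights / s2
        if np.isnan(rinv).any():
            raise ValueError("observations not covered by residual classes")
        self.rinv = rinv

        # --- choose absorbed term --------------------------------------
        self.absorb_idx: int | None = None
        if absorb == "auto":
            cands = [(t.q, i) for i, t in enumerate(terms) if t.absorbable()]
            if cands:
                self.absorb_idx = max(cands)[1]
        elif absorb is not None:
            self.absorb_idx = next(i for i, t in enumerate(terms) if t.name == absorb)
            if not terms[self.absorb_idx].absorbable():
                raise ValueError(f"term {absorb!r} is not absorbable")

        # --- column layout: X, core terms..., absorbed term last -------
        order = [i for i in range(len(terms)) if i != self.absorb_idx]
        if self.absorb_idx is not None:
            order.append(self.absorb_idx)
        self.term_order = order
        blocks = [sparse.csr_matrix(self.X)] + [terms[i].Z for i in order]
        self.TX = sparse.hstack(blocks, format="csc")
        self.col_offsets = {}
        off = self.p
        for i in order:
            self.col_offsets[terms[i].name] = (off, off + terms[i].q)
            off += terms[i].q
        self.n_coef = off
        if self.absorb_idx is not None:
            self.m_core = self.n_coef - terms[self.absorb_idx].q
        else:
            self.m_core = self.n_coef
        self.q_abs = self.n_coef - self.m_core

        self._assemble()

    # ------------------------------------------------------------------
    def _ginv_logdet_blocks(self):
        """Per-term covariance inverse contribution and log|G_k|."""
        ginvs, logdets = [], []
        for t, sl in zip(self.terms, self.term_param_slices):
            th = self.theta[sl]
            if t.kind == "iid":
                s2 = th[0]
                ginvs.append(("diag", 1.0 / s2))
                logdets.append(t.q * np.log(s2))
            elif t.kind == "grm":
                s2 = th[0]
                ginvs.append(("dense", t.grm.inverse() / s2))
                logdets.append(t.q * np.log(s2) + t.grm.logdet())
            else:
                T = bivariate_trait_cov(*th)
                detT = T[0, 0] * T[1, 1] - T[0, 1] ** 2
                if detT <= 0 or T[0, 0] <= 0:
                    raise np.linalg.LinAlgError(
                        f"trait covariance of {t.name!r} not positive definite: {T}")
                Tinv = np.array([[T[1, 1], -T[0, 1]], [-T[0, 1], T[0, 0]]]) / detT
                ginv = np.kron(Tinv, t.grm.inverse())
                ginvs.append(("dense", ginv))
                logdets.append(t.grm.n_lines * np.log(detT) + 2.0 * t.grm.logdet())
        return ginvs, logdets

    def _assemble(self):
        TX = self.TX
        rinv = self.rinv
        # C_t = TX' R^-1 TX (sparse)
        RTX = TX.multiply(rinv[:, None]).tocsc()
        Ct = (TX.T @ RTX).tocsc()
        ginvs, logdets = self._ginv_logdet_blocks()
        self.logdet_G = float(sum(logdets))

        mc, qa = self.m_core, self.q_abs
        C_cc = Ct[:mc, :mc].toarray()
        if qa:
            C_cf = Ct[:mc, mc:].tocsc()
            abs_term = self.terms[self.absorb_idx]
            abs_sl = self.term_param_slices[self.absorb_idx]
            cff = Ct[mc:, mc:].diagonal() + 1.0 / self.theta[abs_sl][0]
            # absorbed block must be structurally diagonal
            self.cff = cff
            E = C_cf.multiply(1.0 / cff[None, :]).tocsc()
            S = C_cc - (E @ C_cf.T).toarray()
            self.C_cf = C_cf
            self.E = E
        else:
            self.cff = np.empty(0)
            self.C_cf = None
            self.E = None
            S = C_cc
        # add covariance inverses of core terms
        for i in self.term_order:
            if i == self.absorb_idx:
                continue
            t = self.terms[i]
            a, b = self.col_offsets[t.name]
            kind, val = ginvs[i]
            if kind == "diag":
                S[np.arange(a, b), np.arange(a, b)] += val
            else:
                S[a:b, a:b] += val
        self.S = S
        self.cho = cho_factor(S, lower=True)
        self.logdet_C = 2.0 * float(np.log(np.diag(self.cho[0])).sum())
        if qa:
            self.logdet_C += float(np.log(self.cff).sum())

        self._S_inv = None
        self._M = None
        self._dff = None
        self._leverages = None

        # solve for BLUE/BLUP
        rhs = TX.T @ (rinv * self.y)
        self.rhs = rhs
        self.sol = self.solve(rhs)
        self.fitted = TX @ self.sol
        self.resid = self.y - self.fitted
        self.Py = rinv * self.resid
        self.yPy = float(self.y @ (rinv * self.y) - self.sol @ rhs)

    # ------------------------------------------------------------------
    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve C x = rhs for one or more right-hand sides (columns)."""
        rhs = np.asarray(rhs, dtype=float)
        one_d = rhs.ndim == 1
        if one_d:
            rhs = rhs[:, None]
        mc = self.m_core
        r_c, r_f = rhs[:mc], rhs[mc:]
        if self.q_abs:
            u0 = r_f / self.cff[:, None]
            x_c = cho_solve(self.cho, r_c - self.C_cf @ u0)
            x_f = (r_f - self.C_cf.T @ x_c) / self.cff[:, None]
            x = np.vstack([x_c, x_f])
        else:
            x = cho_solve(self.cho, r_c)
        return x[:, 0] if one_d else x

    @property
    def S_inv(self) -> np.ndarray:
        if self._S_inv is None:
            from scipy.linalg.lapack import dpotri
            inv, info = dpotri(self.cho[0], lower=True)
            if info != 0:  # pragma: no cover - cho_factor already succeeded
                raise np.linalg.LinAlgError(f"dpotri failed (info={info})")
            inv = np.tril(inv) + np.tril(inv, -1).T
            self._S_inv = inv
        return self._S_inv

    @property
    def M(self) -> np.ndarray:
        """S^{-1} E, so that C^{-1}[core, abs] = -M."""
        if self._M is None:
            if self.q_abs:
                self._M = np.asarray((self.E.T @ self.S_inv).T)
            else:
                self._M = np.zeros((self.m_core, 0))
        return self._M

    @property
    def dff(self) -> np.ndarray:
        """diag of C^{-1} over the absorbed block."""
        if self._dff is None:
            if self.q_abs:
                corr = np.asarray(self.E.multiply(self.M).sum(axis=0)).ravel()
                self._dff = 1.0 / self.cff + corr
            else:
                self._dff = np.empty(0)
        return self._dff

    # ------------------------------------------------------------------
    def leverages(self) -> np.ndarray:
        """Diagonal of the hat matrix H = [X Z] C^{-1} [X Z]' R^{-1}."""
        if self._leverages is not None:
            return self._leverages
        mc = self.m_core
        if not hasattr(self, "_TXc"):
            self._TXc = self.TX[:, :mc].tocsr()
        TXc = self._TXc
        Q = TXc @ self.S_inv                      # n x core (dense)
        a = np.asarray(TXc.multiply(Q).sum(axis=1)).ravel()
        if self.q_abs:
            A = self.TX[:, mc:].tocsr()
            coo = A.tocoo()
            j_of_row = np.full(self.n_obs, -1, dtype=int)
            v_of_row = np.zeros(self.n_obs)
            j_of_row[coo.row] = coo.col
            v_of_row[coo.row] = coo.data
            # cross term: -2 v * sum_k TXc[n,k] M[k, j_n]
            cc = TXc.tocoo()
            has = j_of_row[cc.row] >= 0
            contrib = np.zeros(self.n_obs)
            np.add.at(contrib, cc.row[has],
                      cc.data[has] * self.M[cc.col[has], j_of_row[cc.row[has]]])
            b = -2.0 * v_of_row * contrib
            c = np.where(j_of_row >= 0, v_of_row ** 2 * self.dff[np.maximum(j_of_row, 0)], 0.0)
            tct = a + b + c
        else:
            tct = a
        lev = self.rinv * tct
        self._leverages = np.clip(lev, 0.0, 1.0 - 1e-12)
        return self._leverages

    # ------------------------------------------------------------------
    def cinv_submatrix(self, ids: np.ndarray) -> np.ndarray:
        """Dense C^{-1}[ids, ids] for arbitrary coefficient indices."""
        ids = np.asarray(ids, dtype=int)
        mc = self.m_core
        core = ids < mc
        out = np.empty((len(ids), len(ids)))
        ic, ia = ids[core], ids[~core] - mc
        Scc = self.S_inv[np.ix_(ic, ic)]
        out[np.ix_(core, core)] = Scc
        if (~core).any():
            Mca = self.M[np.ix_(ic, ia)]
            out[np.ix_(core, ~core)] = -Mca
            out[np.ix_(~core, core)] = -Mca.T
            # abs-abs: delta/cff + E_j' S^{-1} E_j' = delta/cff + (E' M)
            Ea = self.E[:, ia]                     # core x |ia| sparse
            block = np.asarray(Ea.T @ self.M[:, ia])
            block = 0.5 * (block + block.T)
            block[np.diag_indices_from(block)] += 1.0 / self.cff[ia]
            out[np.ix_(~core, ~core)] = block
        return out

    def cinv_block(self, name_or_slice) -> np.ndarray:
        """C^{-1} block of one random term (needed for traces/EM updates)."""
        if isinstance(name_or_slice, str):
            a, b = self.col_offsets[name_or_slice]
        else:
            a, b = name_or_slice
        if b <= self.m_core:
            return self.S_inv[a:b, a:b]
        raise ValueError("cinv_block of the absorbed term is diagonal; use dff")

    def term_solution(self, name: str) -> np.ndarray:
        a, b = self.col_offsets[name]
        return self.sol[a:b]

    @property
    def beta(self) -> np.ndarray:
        return self.sol[: self.p]

    # ------------------------------------------------------------------
    def reml_loglik(self) -> float:
        """-0.5 (log|R| + log|G| + log|C| + y'Py), constants dropped."""
        logdet_R = -float(np.log(self.rinv).sum())
        return -0.5 * (logdet_R + self.logdet_G + self.logdet_C + self.yPy)
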