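"""Average-information REML for mixed models with correlated random effects.

Supports iid and GRM-correlated random terms, a two-trait GRM term with an
unstructured 2x2 trait covariance, and heterogeneous residual classes with
known per-observation weights.  Updates are Newton steps on the variance
parameters using the average-information (AI) matrix, with step halving and
an expectation-maximization (EM) fallback whenever an AI step leaves the
parameter space or decreases the restricted likelihood.  Variances reaching
the floor 1e-10 are pinned at the boundary; the implied trait correlation is
constrained to [-0.999, 0.999].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mme import MMESystem, RandomTerm, ResidualClass

VAR_FLOOR = 1e-10
# GRM-correlated variances get a larger boundary floor: their ridge in the
# mixed-model equations is G^{-1}/sigma2, and a GRM regularized out of exact
# singularity has a large-norm inverse, so a 1e-10 variance would put
# astronomically ill-conditioned blocks into the equations.
VAR_FLOOR_COR = 1e-6
MAX_CORR = 0.999


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class VCEstimates:
    """Variance/covariance estimates with asymptotic standard errors."""

    names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)
    pinned: np.ndarray = None  # type: ignore[assignment]

    def as_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self.names, self.estimates)}

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])


class REMLResults:
    """Converged REML fit: variance components, BLUEs/BLUPs, diagnostics."""

    def __init__(self, model: "MixedModel", vc: VCEstimates, system: MMESystem):
        self.model = model
        self.vc = vc
        self.system = system
        self.loglik = vc.loglik
        self.converged = vc.converged

    @property
    def beta(self) -> np.ndarray:
        return self.system.beta

    def blup(self, name: str) -> np.ndarray:
        return self.system.term_solution(name)

    @property
    def resid(self) -> np.ndarray:
        return self.system.resid

    @property
    def fitted(self) -> np.ndarray:
        return self.system.fitted

    def leverages(self) -> np.ndarray:
        return self.system.leverages()


class MixedModel:
    """A mixed model defined by response, fixed design, random terms and
    residual classes; ``fit`` runs AI-REML."""

    def __init__(self, y: np.ndarray, X: np.ndarray, terms: list[RandomTerm],
                 classes: list[ResidualClass],
                 fixed_params: dict[str, float] | None = None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.terms = terms
        self.classes = classes
        self.param_names = [p for t in terms for p in t.param_names] + \
            [f"resid:{c.name}" for c in classes]
        self.fixed_params = dict(fixed_params or {})
        unknown = set(self.fixed_params) - set(self.param_names)
        if unknown:
            raise ValueError(f"fixed_params refer to unknown parameters {unknown}")
        self.fixed_mask = np.array([p in self.fixed_params
                                    for p in self.param_names])
        floors = []
        for t in terms:
            if t.kind == "iid":
                floors.append(VAR_FLOOR)
            elif t.kind == "grm":
                floors.append(VAR_FLOOR_COR)
            else:
                floors += [VAR_FLOOR_COR, -np.inf, VAR_FLOOR_COR]
        floors += [VAR_FLOOR] * len(classes)
        self._floor = np.array(floors)
        self.k_term = sum(t.n_params for t in terms)
        self._term_slices = []
        off = 0
        for t in terms:
            self._term_slices.append(slice(off, off + t.n_params))
            off += t.n_params
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")

    # ------------------------------------------------------------------
    def default_start(self) -> np.ndarray:
        vy = float(np.var(self.y))
        vy = vy if vy > 0 else 1.0
        k_random = sum(1 if t.kind != "grm_bivariate" else 2 for t in self.terms)
        share = 0.5 * vy / max(k_random, 1)
        theta = []
        for t in self.terms:
            if t.kind == "grm_bivariate":
                theta += [share, 0.0, share]
            else:
                theta += [share]
        theta += [0.5 * vy] * len(self.classes)
        return np.array(theta)

    def assemble(self, theta: np.ndarray) -> MMESystem:
        return MMESystem(self.X, self.terms, self.classes, self.y,
                         theta, self.param_names)

    def reml_loglik(self, theta: np.ndarray) -> float:
        """Restricted log-likelihood at ``theta`` (constants dropped)."""
        return self.assemble(np.asarray(theta, float)).reml_loglik()

    # ------------------------------------------------------------------
    def _project(self, theta: np.ndarray) -> np.ndarray:
        th = np.maximum(theta, self._floor)
        for t, sl in zip(self.terms, self._term_slices):
            if t.kind == "grm_bivariate":
                i0 = sl.start
                if th[i0] <= self._floor[i0] * 1.01 or \
                        th[i0 + 2] <= self._floor[i0 + 2] * 1.01:
                    # a boundary variance makes any covariance meaningless and
                    # the trait covariance numerically singular
                    th[i0 + 1] = 0.0
                else:
                    bound = MAX_CORR * np.sqrt(th[i0] * th[i0 + 2])
                    th[i0 + 1] = np.clip(th[i0 + 1], -bound, bound)
        for name, val in self.fixed_params.items():
            th[self.param_names.index(name)] = val
        return th

    def _working_vectors(self, system: MMESystem) -> np.ndarray:
        """Columns w_i = (dV/dtheta_i) P y for every parameter."""
        Py = system.Py
        n = system.n_obs
        W = np.zeros((n, len(self.param_names)))
        col = 0
        for t in self.terms:
            v = t.Z.T @ Py
            if t.kind == "iid":
                W[:, col] = t.Z @ v
                col += 1
            elif t.kind == "grm":
                W[:, col] = t.Z @ (t.grm.values @ v)
                col += 1
            else:
                nl = t.grm.n_lines
                gv1 = t.grm.values @ v[:nl]
                gv2 = t.grm.values @ v[nl:]
                z = np.zeros(nl)
                W[:, col] = t.Z @ np.concatenate([gv1, z])
                W[:, col + 1] = t.Z @ np.concatenate([gv2, gv1])
                W[:, col + 2] = t.Z @ np.concatenate([z, gv2])
                col += 3
        for c in self.classes:
            w = np.zeros(n)
            w[c.index] = Py[c.index] / c.weights
            W[:, col] = w
            col += 1
        return W

    def _traces(self, system: MMESystem) -> np.ndarray:
        """tr(P dV/dtheta_i) for every parameter."""
        tr = np.zeros(len(self.param_names))
        # hat-diagonals are only needed for free residual scales; when all
        # residual classes are fixed (weight matrices fully specify them)
        # the leverage pass is skipped
        any_free_class = any(f"resid:{c.name}" not in self.fixed_params
                             for c in self.classes)
        lev = system.leverages() if any_free_class else None
        col = 0
        for ti, t in enumerate(self.terms):
            sl = self._term_slices[ti]
            th = system.theta[sl]
            if t.kind == "iid":
                s2 = th[0]
                if ti == system.absorb_idx:
                    tr_cuu = float(system.dff.sum())
                else:
                    a, b = system.col_offsets[t.name]
                    tr_cuu = float(np.trace(system.S_inv[a:b, a:b]))
                tr[col] = t.q / s2 - tr_cuu / s2 ** 2
                col += 1
            elif t.kind == "grm":
                s2 = th[0]
                B = system.cinv_block(t.name)
                tr_cuu = float(np.sum(B * t.grm.inverse()))
                tr[col] = t.q / s2 - tr_cuu / s2 ** 2
                col += 1
            else:
                nl = t.grm.n_lines
                T = np.array([[th[0], th[1]], [th[1], th[2]]])
                tinv = np.linalg.inv(T)
                ginv = t.grm.inverse()
                B = system.cinv_block(t.name)
                tau = np.empty((2, 2))
                for a in range(2):
                    for b in range(2):
                        tau[a, b] = np.sum(B[a * nl:(a + 1) * nl,
                                             b * nl:(b + 1) * nl] * ginv)
                for e_mat in (np.array([[1.0, 0.0], [0.0, 0.0]]),
                              np.array([[0.0, 1.0], [1.0, 0.0]]),
                              np.array([[0.0, 0.0], [0.0, 1.0]])):
                    F = e_mat @ tinv
                    tr[col] = nl * np.trace(F) - np.trace(F @ tau @ tinv)
                    col += 1
        for ci, c in enumerate(self.classes):
            if lev is None:
                col += 1
                continue
            s2 = system.class_sigma2[ci]
            tr[col] = float((1.0 - lev[c.index]).sum()) / s2
            col += 1
        return tr

    def _score_ai(self, system: MMESystem):
        Wmat = self._working_vectors(system)
        tr = self._traces(system)
        quad = Wmat.T @ system.Py
        score = -0.5 * (tr - quad)
        rinv = system.rinv
        RHS = system.TX.T @ (rinv[:, None] * Wmat)
        SolM = system.solve(RHS)
        PW = rinv[:, None] * (Wmat - system.TX @ SolM)
        AI = 0.5 * (Wmat.T @ PW)
        AI = 0.5 * (AI + AI.T)
        return score, AI

    def _em_update(self, system: MMESystem) -> np.ndarray:
        theta = system.theta.copy()
        for ti, t in enumerate(self.terms):
            sl = self._term_slices[ti]
            u = system.term_solution(t.name)
            if t.kind == "iid":
                if ti == system.absorb_idx:
                    tr_cuu = float(system.dff.sum())
                else:
                    a, b = system.col_offsets[t.name]
                    tr_cuu = float(np.trace(system.S_inv[a:b, a:b]))
                theta[sl.start] = (u @ u + tr_cuu) / t.q
            elif t.kind == "grm":
                ginv = t.grm.inverse()
                B = system.cinv_block(t.name)
                theta[sl.start] = (u @ ginv @ u + np.sum(B * ginv)) / t.q
            else:
                nl = t.grm.n_lines
                ginv = t.grm.inverse()
                B = system.cinv_block(t.name)
                u1, u2 = u[:nl], u[nl:]
                gu1, gu2 = ginv @ u1, ginv @ u2
                tau = np.empty((2, 2))
                for a in range(2):
                    for b in range(2):
                        tau[a, b] = np.sum(B[a * nl:(a + 1) * nl,
                                             b * nl:(b + 1) * nl] * ginv)
                t11 = (u1 @ gu1 + tau[0, 0]) / nl
                t12 = (u1 @ gu2 + 0.5 * (tau[0, 1] + tau[1, 0])) / nl
                t22 = (u2 @ gu2 + tau[1, 1]) / nl
                theta[sl.start:sl.start + 3] = (t11, t12, t22)
        e = system.resid
        free = [ci for ci, c in enumerate(self.classes)
                if f"resid:{c.name}" not in self.fixed_params]
        if free:
            lev = system.leverages()
            for ci in free:
                c = self.classes[ci]
                idx = c.index
                num = float((c.weights * e[idx] ** 2).sum()
                            + system.class_sigma2[ci] * lev[idx].sum())
                theta[self.k_term + ci] = num / len(idx)
        return self._project(theta)

    # ------------------------------------------------------------------
    def fit(self, start: np.ndarray | None = None, tol: float = 1e-8,
            max_iter: int = 200, verbose: bool = False) -> REMLResults:
        """Run AI-REML to a stationary point of the restricted likelihood."""
        theta = self._project(np.asarray(start, float) if start is not None
                              else self.default_start())
        system = self.assemble(theta)
        ll = system.reml_loglik()
        trace: list[dict] = []
        k = len(self.param_names)
        pinned = np.zeros(k, dtype=bool)
        AI = np.eye(k)
        converged = False
        n_iter = 0
        # boundary lock for the bivariate correlation: once the implied
        # correlation presses outward on its |rho| <= MAX_CORR bound for two
        # consecutive iterations, the covariance is slaved to the variances
        # (cov = sign * MAX_CORR * sqrt(v1 v2)) so the remaining parameters
        # can converge instead of zigzagging along the constraint
        biv_idx = [sl.start for t, sl in zip(self.terms, self._term_slices)
                   if t.kind == "grm_bivariate"]
        rho_streak = {i0: 0 for i0 in biv_idx}
        rho_lock: dict[int, float] = {}

        def enforce_locks(th):
            for i0, sign in rho_lock.items():
                th[i0 + 1] = sign * MAX_CORR * np.sqrt(th[i0] * th[i0 + 2])
            return th

        for n_iter in range(1, max_iter + 1):
            score, AI = self._score_ai(system)
            # pin variances stuck at the floor with downhill gradient
            is_var = np.ones(k, dtype=bool)
            for t, sl in zip(self.terms, self._term_slices):
                if t.kind == "grm_bivariate":
                    is_var[sl.start + 1] = False
            at_floor = theta <= self._floor * 1.01
            pinned = (is_var & at_floor & (score < 0)) | self.fixed_mask
            # a covariance is frozen along with either of its variances, and
            # when the implied correlation presses outward on its |rho| bound
            for t, sl in zip(self.terms, self._term_slices):
                if t.kind == "grm_bivariate":
                    i0, cj = sl.start, sl.start + 1
                    if pinned[i0] or pinned[i0 + 2]:
                        pinned[cj] = True
                        continue
                    bound = MAX_CORR * np.sqrt(theta[i0] * theta[i0 + 2])
                    outward = (abs(theta[cj]) >= 0.995 * bound
                               and score[cj] * np.sign(theta[cj]) > 0)
                    if i0 in rho_lock:
                        # sticky within one fit: releasing on any inward score
                        # flap re-creates the zigzag the lock exists to stop
                        pinned[cj] = True
                    elif outward:
                        rho_streak[i0] += 1
                        if rho_streak[i0] >= 2:
                            rho_lock[i0] = float(np.sign(theta[cj]))
                            pinned[cj] = True
                    else:
                        rho_streak[i0] = 0
            active = ~pinned
            idx = np.where(active)[0]
            ai_act = AI[np.ix_(idx, idx)]
            # ridge for safety on near-singular AI
            ai_act = ai_act + 1e-10 * np.eye(len(idx)) * max(np.trace(ai_act), 1.0)
            try:
                delta = np.linalg.solve(ai_act, score[idx])
            except np.linalg.LinAlgError:
                delta = score[idx] / np.maximum(np.diag(ai_act), 1e-8)
            accepted = False
            step = 1.0
            for _ in range(12):
                cand = theta.copy()
                cand[idx] += step * delta
                cand = enforce_locks(self._project(cand))
                try:
                    system2 = self.assemble(cand)
                    ll2 = system2.reml_loglik()
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if np.isfinite(ll2) and ll2 >= ll - 1e-9 * (abs(ll) + 1.0):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                cand = enforce_locks(self._em_update(system))
                system2 = self.assemble(cand)
                ll2 = system2.reml_loglik()
            moved = np.abs(cand - theta) / (np.abs(theta) + 1e-5)
            moved[pinned] = 0.0
            rel = float(moved.max()) if k else 0.0
            dll = ll2 - ll
            theta, system, ll = cand, system2, ll2
            trace.append({"iter": n_iter, "loglik": float(ll),
                          "theta": theta.tolist(), "rel_change": rel,
                          "step": step if accepted else "EM"})
            if verbose:  # pragma: no cover
                print(f"iter {n_iter}: ll={ll:.6f} rel={rel:.2e}")
            if rel < tol:
                converged = True
                break
            # stationary-likelihood stop: two consecutive negligible gains
            if len(trace) >= 3 and abs(dll) < 1e-9 * (1.0 + abs(ll)):
                prev_dll = trace[-2]["loglik"] - trace[-3]["loglik"]
                if abs(prev_dll) < 1e-9 * (1.0 + abs(ll)):
                    converged = True
                    break
            # windowed stationarity: boundary-degenerate fits wobble inside
            # the numerical noise floor of the likelihood without ever making
            # progress; stop once both the likelihood range and the parameter
            # moves over the last several iterations are negligible
            if len(trace) >= 8:
                lls = [tr_["loglik"] for tr_ in trace[-8:]]
                rels = [tr_["rel_change"] for tr_ in trace[-8:]]
                if (max(lls) - min(lls)) < 1e-6 * (1.0 + abs(ll)) \
                        and max(rels) < 1e-3:
                    converged = True
                    break
        if not converged:
            raise ConvergenceError(
                f"AI-REML did not converge in {max_iter} iterations "
                f"(last relative change {trace[-1]['rel_change']:.3e})", trace)
        # asymptotic SEs from the AI matrix at convergence
        score, AI = self._score_ai(system)
        se = np.full(k, np.nan)
        idx = np.where(~pinned)[0]
        try:
            cov = np.linalg.inv(AI[np.ix_(idx, idx)])
            se[idx] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
        vc = VCEstimates(names=list(self.param_names), estimates=theta.copy(),
                         se=se, loglik=float(ll), converged=True,
                         n_iter=n_iter, trace=trace, pinned=pinned)
        return REMLResults(self, vc, system)


def compute_leverages(fit: REMLResults) -> np.ndarray:
    """Hat-matrix diagonal of a converged fit; values in [0, 1)."""
    return fit.leverages()


@dataclass
class GammaGLMFit:
    """Weighted gamma GLM (log link) fit with its IRLS linearization."""

    coef: np.ndarray
    fitted: np.ndarray
    eta: np.ndarray
    working_response: np.ndarray
    deviance: float
    offset: np.ndarray | None = None


def weighted_gamma_glm(y_d: np.ndarray, X_d: np.ndarray,
                       weights: np.ndarray | None = None,
                       offset: np.ndarray | None = None,
                       tol: float = 1e-8, max_iter: int = 100) -> GammaGLMFit:
    """Weighted gamma GLM with a log link.

    Returns the coefficient vector, fitted means, and the IRLS working
    response z = eta + (y - mu) / mu on the log scale, which carries the
    dispersion response into the bivariate mixed-model step.
    """
    import statsmodels.api as sm

    y_d = np.asarray(y_d, dtype=float)
    if (y_d <= 0).any():
        raise ValueError("gamma GLM response must be strictly positive "
                         "(non-positive dispersion response signals an "
                         "upstream leverage or residual fault)")
    X_d = np.asarray(X_d, dtype=float)
    if weights is None:
        weights = np.ones_like(y_d)
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be >= 0")
    if np.ptp(y_d) <= 1e-12 * abs(y_d[0]):
        # constant response saturates an intercept: deviance 0, mu = c
        eta = np.full_like(y_d, np.log(y_d[0]))
        if offset is not None:
            eta = eta  # the linear predictor still reproduces log(c)
        coef, *_ = np.linalg.lstsq(
            X_d, eta - (0.0 if offset is None else np.asarray(offset)),
            rcond=None)
        mu = np.full_like(y_d, y_d[0])
        return GammaGLMFit(coef=coef, fitted=mu, eta=eta,
                           working_response=eta, deviance=0.0, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y_d, X_d,
                       family=sm.families.Gamma(link=sm.families.links.Log()),
                       var_weights=weights, offset=offset)
        res = model.fit(tol=tol, maxiter=max_iter)
    mu = np.asarray(res.fittedvalues)
    eta = np.log(mu)
    z = eta + (y_d - mu) / mu
    return GammaGLMFit(coef=np.asarray(res.params), fitted=mu, eta=eta,
                       working_response=z, deviance=float(res.deviance),
                       offset=offset)
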