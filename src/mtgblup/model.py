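"""Single- and multiple-trait animal models: BLUP/GBLUP solving and REML.

The model is ``y = 1 mu + Z g + e`` per trait, with genetic values
``g ~ N(0, K (x) H)`` for a relationship matrix K (pedigree A or genomic G)
and trait covariance H, and residuals ``e ~ N(0, I (x) R)``.  Records may be
missing per trait; a record unit (one row of the response table) couples its
observed traits through R.  Fixed effects are intercepts only, one per
trait.

Solving goes through Henderson's mixed-model equations, assembled sparse
when K^-1 is sparse (pedigree) and dense otherwise (genomic).  Variance
components are estimated by REML: average-information (AI) updates with
exact gradients in a dense observation-scale formulation, an EM algorithm
for complete-pattern data, and a derivative-free simplex search on the
restricted log-likelihood that works at any scale the factorization
supports and serves as an independent cross-check of AI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu

from .kinship import RelationshipMatrix

_LOG2PI = np.log(2.0 * np.pi)


class ModelError(ValueError):
    pass


class SingularSystemError(np.linalg.LinAlgError):
    pass


@dataclass
class VarianceComponents:
    """Genetic (H) and residual (R) trait covariance matrices.

    For a single trait these are the scalars sigma_g^2 and sigma_e^2 stored
    as 1x1 matrices.  ``log_likelihood`` is the restricted log-likelihood at
    (H, R) when produced by REML.
    """

    H: np.ndarray
    R: np.ndarray
    converged: bool = True
    log_likelihood: float = np.nan
    iterations: int = 0
    method: str = "fixed"

    def __post_init__(self):
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        for name, m in (("H", self.H), ("R", self.R)):
            if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
                raise ModelError(f"{name} must be a symmetric square matrix")
        if self.H.shape != self.R.shape:
            raise ModelError("H and R must have matching trait dimension")

    @property
    def n_traits(self) -> int:
        return self.H.shape[0]

    @property
    def heritabilities(self) -> np.ndarray:
        return np.diag(self.H) / (np.diag(self.H) + np.diag(self.R))

    @property
    def genetic_correlation(self) -> float:
        if self.n_traits < 2:
            raise ModelError("genetic correlation needs two traits")
        return self.H[0, 1] / np.sqrt(self.H[0, 0] * self.H[1, 1])


def _is_pd(m: np.ndarray, tol: float = 0.0) -> bool:
    try:
        sla.cholesky(m - tol * np.eye(m.shape[0]), lower=True)
        return True
    except np.linalg.LinAlgError:
        return False


def _chol_params_to_mats(theta: np.ndarray, t: int):
    """Map unconstrained simplex parameters to (H, R) via Cholesky factors."""
    k = t * (t + 1) // 2

    def build(v):
        L = np.zeros((t, t))
        pos = 0
        for i in range(t):
            for j in range(i + 1):
                L[i, j] = np.exp(v[pos]) if i == j else v[pos]
                pos += 1
        return L @ L.T

    return build(theta[:k]), build(theta[k:])


def _mats_to_chol_params(H: np.ndarray, R: np.ndarray) -> np.ndarray:
    t = H.shape[0]

    def take(m):
        L = sla.cholesky(m, lower=True)
        out = []
        for i in range(t):
            for j in range(i + 1):
                out.append(np.log(L[i, j]) if i == j else L[i, j])
        return out

    return np.array(take(H) + take(R))


def _theta_to_mats(theta: np.ndarray, t: int):
    """Raw-parameter layout used by AI: unique elements of H then R."""
    k = t * (t + 1) // 2

    def build(v):
        m = np.zeros((t, t))
        pos = 0
        for i in range(t):
            for j in range(i + 1):
                m[i, j] = m[j, i] = v[pos]
                pos += 1
        return m

    return build(theta[:k]), build(theta[k:])


def _mats_to_theta(H, R):
    t = H.shape[0]

    def take(m):
        return [m[i, j] for i in range(t) for j in range(i + 1)]

    return np.array(take(H) + take(R))


class AnimalModel:
    """Animal model linking trait records to a relationship matrix.

    Parameters
    ----------
    data : DataFrame with an animal-id column and one column per trait;
        NaN marks a missing record for that trait.  An animal may appear in
        several rows (repeated records), each row being an independent
        residual unit.
    kinship : RelationshipMatrix covering every animal in ``data`` (animals
        present only in the kinship receive predictions but contribute no
        records).
    traits : sequence of 1 or 2 response column names.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        kinship: RelationshipMatrix,
        traits,
        animal_col: str = "animal_id",
        mme_exact_limit: int = 20_000,
        ai_obs_limit: int = 3000,
        pev_limit: int = 50_000,
    ):
        self.kinship = kinship
        self.traits = list(traits)
        self.t = len(self.traits)
        if self.t not in (1, 2):
            raise ModelError("one or two traits supported")
        self.mme_exact_limit = mme_exact_limit
        self.ai_obs_limit = ai_obs_limit
        self.pev_limit = pev_limit

        Y = data[self.traits].to_numpy(dtype=float)
        keep = ~np.all(np.isnan(Y), axis=1)
        self.Y = Y[keep]
        self.unit_animal = kinship.positions(data.loc[keep, animal_col])
        self.n_units = self.Y.shape[0]
        if self.n_units == 0:
            raise ModelError("no records")
        obs_mask = ~np.isnan(self.Y)
        per_trait = obs_mask.sum(axis=0)
        if np.any(per_trait == 0):
            raise ModelError(
                f"trait(s) {np.array(self.traits)[per_trait == 0]} have no records"
            )
        self.n_obs = int(obs_mask.sum())
        self._obs_mask = obs_mask
        # pattern groups: units sharing the same observed-trait mask
        codes = obs_mask @ (1 << np.arange(self.t))
        self._patterns = []
        for code in np.unique(codes):
            tr = np.flatnonzero([(code >> a) & 1 for a in range(self.t)])
            units = np.flatnonzero(codes == code)
            self._patterns.append((tr, units))
        self.q = kinship.n
        self.n_eq = self.t + self.q * self.t
        self._sparse = sp.issparse(kinship.matrix)

    # ------------------------------------------------------------------ MME
    def _data_entries(self, R: np.ndarray):
        """COO entries of the data part of the MME plus rhs, y'R^-1 y and
        log|R_big|."""
        t, p = self.t, self.t
        rows, cols, vals = [], [], []
        rhs = np.zeros(self.n_eq)
        yry = 0.0
        logdet_r = 0.0
        for tr, units in self._patterns:
            Rs = R[np.ix_(tr, tr)]
            try:
                Rs_inv = sla.inv(Rs)
            except np.linalg.LinAlgError as exc:
                raise SingularSystemError(
                    f"residual covariance singular on pattern {tr}"
                ) from exc
            sign, ld = np.linalg.slogdet(Rs)
            if sign <= 0:
                raise ModelError("R must be positive definite on every pattern")
            logdet_r += ld * units.size
            a = self.unit_animal[units]
            yv = self.Y[np.ix_(units, tr)]
            for ia, ta in enumerate(tr):
                for ib, tb in enumerate(tr):
                    w = Rs_inv[ia, ib]
                    # fixed x fixed
                    rows.append(np.array([ta]))
                    cols.append(np.array([tb]))
                    vals.append(np.array([w * units.size]))
                    # fixed x random and transpose
                    gcol = p + a * t + tb
                    rows.append(np.full(a.size, ta))
                    cols.append(gcol)
                    vals.append(np.full(a.size, w))
                    rows.append(gcol)
                    cols.append(np.full(a.size, ta))
                    vals.append(np.full(a.size, w))
                    # random x random
                    rows.append(p + a * t + ta)
                    cols.append(gcol)
                    vals.append(np.full(a.size, w))
                np.add.at(rhs, np.array([ta]), (Rs_inv[ia] @ yv.T).sum())
                np.add.at(rhs, p + a * t + ta, yv @ Rs_inv[ia])
            yry += float(np.einsum("ui,ij,uj->", yv, Rs_inv, yv))
        return (
            np.concatenate(rows),
            np.concatenate(cols),
            np.concatenate(vals),
            rhs,
            yry,
            logdet_r,
        )


    def _assemble(self, H: np.ndarray, R: np.ndarray):
        if np.any(np.diag(H) <= 0):
            raise ModelError("genetic variances must be positive")
        try:
            H_inv = sla.inv(H)
            sign, logdet_h = np.linalg.slogdet(H)
            if sign <= 0:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError as exc:
            raise SingularSystemError(
                "H is singular; perfect genetic correlations need a small "
                "jitter on H before solving"
            ) from exc
        kinv, logdet_k = self.kinship.precision()
        rows, cols, vals, rhs, yry, logdet_r = self._data_entries(R)
        p = self.t
        if self._sparse:
            data_part = sp.coo_matrix(
                (vals, (rows, cols)), shape=(self.n_eq, self.n_eq)
            )
            gen = sp.kron(kinv, sp.csr_matrix(H_inv), format="coo")
            gen = sp.coo_matrix(
                (gen.data, (gen.row + p, gen.col + p)),
                shape=(self.n_eq, self.n_eq),
            )
            C = (data_part + gen).tocsc()
        else:
            C = np.zeros((self.n_eq, self.n_eq))
            np.add.at(C, (rows, cols), vals)
            C[p:, p:] += np.kron(np.asarray(kinv), H_inv)
        extra = logdet_r + self.t * logdet_k + self.q * logdet_h
        return C, rhs, yry, extra

    def _solve_cg(self, C, rhs):
        """Jacobi-preconditioned conjugate gradients for very large MMEs.

        Gives solutions only: no log-determinant (so no REML) and no
        coefficient-matrix inverse (so no PEV reliabilities).
        """
        d = C.diagonal()
        M = sp.diags(1.0 / np.where(d > 0, d, 1.0))
        sol, info = sp.linalg.cg(C, rhs, M=M, rtol=1e-10, atol=0.0, maxiter=50_000)
        if info != 0:
            raise SingularSystemError(f"conjugate gradients failed (info={info})")
        return sol

    def _factorize(self, C):
        if self._sparse:
            if self.n_eq > self.mme_exact_limit:
                raise ModelError(
                    f"{self.n_eq} equations exceed the exact-solve limit "
                    f"({self.mme_exact_limit}); only fixed-component solving "
                    "is available at this scale (iterative path)"
                )
            try:
                # MME is structurally symmetric; the AT+A ordering is far
                # sparser than the default COLAMD here
                lu = splu(
                    C,
                    permc_spec="MMD_AT_PLUS_A",
                    options={"SymmetricMode": True, "DiagPivotThresh": 0.0},
                )
            except RuntimeError as exc:
                raise SingularSystemError(str(exc)) from exc
            logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
            return ("sparse", lu), logdet
        try:
            cf = sla.cho_factor(C, lower=True)
        except np.linalg.LinAlgError as exc:
            raise SingularSystemError("MME coefficient matrix not PD") from exc
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return ("dense", cf), logdet

    def _solve_factor(self, factor, b):
        kind, f = factor
        return f.solve(b) if kind == "sparse" else sla.cho_solve(f, b)

    def loglike(self, components) -> float:
        """Restricted log-likelihood at the given variance components."""
        H, R = self._coerce_components(components)
        C, rhs, yry, extra = self._assemble(H, R)
        factor, logdet_c = self._factorize(C)
        sol = self._solve_factor(factor, rhs)
        ypy = yry - float(sol @ rhs)
        return -0.5 * (logdet_c + extra + ypy + (self.n_obs - self.t) * _LOG2PI)

    def _coerce_components(self, components):
        if isinstance(components, VarianceComponents):
            H, R = components.H, components.R
        elif isinstance(components, (tuple, list)) and len(components) == 2:
            H, R = (np.atleast_2d(np.asarray(x, dtype=float)) for x in components)
        else:
            raise ModelError("components must be VarianceComponents or (H, R)")
        if H.shape != (self.t, self.t):
            raise ModelError(f"H must be {self.t}x{self.t}")
        return H, R

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        components=None,
        method: str = "auto",
        start=None,
        maxiter: int = 200,
        xtol: float = 1e-8,
        gtol: float = 1e-6,
    ) -> "AnimalModelResults":
        """Solve the model; estimate variance components by REML first when
        none are supplied.

        method: "ai" (average information; dense observation-scale, for
        moderate record counts), "em" (complete patterns only),
        "direct_search" (Nelder-Mead on the restricted log-likelihood), or
        "auto" (AI when the record count allows, otherwise direct search).
        """
        if components is not None:
            H, R = self._coerce_components(components)
            vc = VarianceComponents(H=H, R=R, method="fixed")
        else:
            vc = self.estimate_reml(
                method=method, start=start, maxiter=maxiter, xtol=xtol, gtol=gtol
            )
        C, rhs, yry, extra = self._assemble(vc.H, vc.R)
        if self._sparse and self.n_eq > self.mme_exact_limit:
            sol = self._solve_cg(C.tocsr(), rhs)
            factor = None
        else:
            factor, logdet_c = self._factorize(C)
            sol = self._solve_factor(factor, rhs)
            ypy = yry - float(sol @ rhs)
            llf = -0.5 * (logdet_c + extra + ypy + (self.n_obs - self.t) * _LOG2PI)
            if vc.method == "fixed":
                vc.log_likelihood = llf
        return AnimalModelResults(
            model=self,
            varcomp=vc,
            intercepts=sol[: self.t].copy(),
            solutions=sol[self.t :].reshape(self.q, self.t).copy(),
            _factor=factor,
        )

    # ----------------------------------------------------------------- REML
    def _reml_start(self, start):
        if start is not None:
            return self._coerce_components(start)
        v = np.nanvar(self.Y, axis=0, ddof=1)
        return 0.5 * np.diag(v), 0.5 * np.diag(v)

    def estimate_reml(
        self,
        method: str = "auto",
        start=None,
        maxiter: int = 200,
        xtol: float = 1e-8,
        gtol: float = 1e-6,
    ) -> VarianceComponents:
        if self._sparse and self.n_eq > self.mme_exact_limit:
            raise ModelError(
                f"REML needs an exact factorization; {self.n_eq} equations "
                f"exceed mme_exact_limit={self.mme_exact_limit}"
            )
        for a in range(self.t):
            col = self.Y[:, a]
            col = col[~np.isnan(col)]
            if np.ptp(col) == 0.0:
                raise ModelError(
                    f"response {self.traits[a]!r} is constant; REML undefined"
                )
        H0, R0 = self._reml_start(start)
        if method == "auto":
            if self.n_obs > self.ai_obs_limit:
                method = "quasi_newton"
            else:
                # AI first; on non-convergence (tiny or boundary problems)
                # polish with the derivative-free search from the AI point
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    vc = self._reml_ai(H0, R0, maxiter, xtol, gtol)
                if vc.converged:
                    return vc
                try:
                    alt = self._reml_quasi_newton(vc.H, vc.R, maxiter)
                except (ModelError, SingularSystemError, np.linalg.LinAlgError):
                    return vc
                return alt if alt.log_likelihood >= vc.log_likelihood else vc
        if method == "ai":
            return self._reml_ai(H0, R0, maxiter, xtol, gtol)
        if method == "em":
            return self._reml_em(H0, R0, maxiter, xtol)
        if method == "direct_search":
            return self._reml_direct(H0, R0, maxiter)
        if method == "quasi_newton":
            return self._reml_quasi_newton(H0, R0, maxiter)
        raise ModelError(f"unknown REML method {method!r}")

    def _reml_direct(self, H0, R0, maxiter) -> VarianceComponents:
        t = self.t
        theta0 = _mats_to_chol_params(H0, R0)

        def neg_llf(theta):
            H, R = _chol_params_to_mats(theta, t)
            try:
                return -self.loglike((H, R))
            except (ModelError, SingularSystemError, np.linalg.LinAlgError):
                return np.inf

        res = minimize(
            neg_llf,
            theta0,
            method="Nelder-Mead",
            options={
                "maxiter": min(max(maxiter, 400 * theta0.size), 2400),
                "xatol": 1e-7,
                "fatol": 1e-9,
                "adaptive": theta0.size > 2,
            },
        )
        H, R = _chol_params_to_mats(res.x, t)
        return VarianceComponents(
            H=H,
            R=R,
            converged=bool(res.success),
            log_likelihood=-float(res.fun),
            iterations=int(res.nit),
            method="direct_search",
        )

    def _reml_quasi_newton(self, H0, R0, maxiter) -> VarianceComponents:
        """L-BFGS-B on the restricted log-likelihood (numerical gradients).

        Used for problems too large for the dense AI formulation; the
        finite-difference step is chosen well above the factorization's
        round-off so the gradients stay smooth.
        """
        t = self.t
        theta0 = _mats_to_chol_params(H0, R0)
        scale = 1.0 / max(self.n_obs, 1)  # O(1) gradients for sane step sizes

        def neg_llf(theta):
            H, R = _chol_params_to_mats(theta, t)
            try:
                return -self.loglike((H, R)) * scale
            except (ModelError, SingularSystemError, np.linalg.LinAlgError):
                return np.inf

        diag = np.zeros(theta0.size, dtype=bool)
        pos = 0
        for block in range(2):
            for i in range(t):
                for j in range(i + 1):
                    diag[pos] = i == j
                    pos += 1
        # bounded log-scale diagonals keep boundary estimates (variance -> 0)
        # from sending the search to -inf
        bounds = [(-8.0, 8.0) if d else (-100.0, 100.0) for d in diag]
        res = minimize(
            neg_llf,
            np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"eps": 1e-5, "maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        H, R = _chol_params_to_mats(res.x, t)
        return VarianceComponents(
            H=H,
            R=R,
            converged=bool(res.success),
            log_likelihood=-float(res.fun) / scale,
            iterations=int(res.nit),
            method="quasi_newton",
        )

    # -- dense observation-scale machinery shared by AI ---------------------
    def _obs_layout(self):
        rec = np.unique(self.unit_animal)
        K = self.kinship.submatrix(rec)
        pos_in_rec = np.searchsorted(rec, self.unit_animal)
        obs_unit, obs_trait = np.nonzero(self._obs_mask)
        obs_animal = pos_in_rec[obs_unit]
        y = self.Y[obs_unit, obs_trait]
        X = np.zeros((y.size, self.t))
        X[np.arange(y.size), obs_trait] = 1.0
        return K, obs_unit, obs_trait, obs_animal, y, X

    def _reml_ai(self, H0, R0, maxiter, xtol, gtol) -> VarianceComponents:
        if self.n_obs > self.ai_obs_limit:
            raise ModelError(
                f"{self.n_obs} records exceed ai_obs_limit="
                f"{self.ai_obs_limit}; use method='direct_search'"
            )
        t = self.t
        K, obs_unit, obs_trait, obs_animal, y, X = self._obs_layout()
        M = K[np.ix_(obs_animal, obs_animal)]
        U = (obs_unit[:, None] == obs_unit[None, :]).astype(float)
        ti, tj = obs_trait[:, None], obs_trait[None, :]
        npar = t * (t + 1)
        pairs = [(i, j) for i in range(t) for j in range(i + 1)]

        def dV(k):
            half = len(pairs)
            base = M if k < half else U
            a, b = pairs[k % half]
            mask = ((ti == a) & (tj == b)) | ((ti == b) & (tj == a))
            return base * mask

        def build_V(H, R):
            return M * H[ti, tj] + U * R[ti, tj]

        def llf_parts(H, R):
            V = build_V(H, R)
            cf = sla.cho_factor(V, lower=True)
            logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
            ViX = sla.cho_solve(cf, X)
            Viy = sla.cho_solve(cf, y)
            XtViX = X.T @ ViX
            beta = sla.solve(XtViX, X.T @ Viy, assume_a="pos")
            Py = Viy - ViX @ beta
            _, ld_x = np.linalg.slogdet(XtViX)
            llf = -0.5 * (
                logdet_v + ld_x + float(y @ Py) + (y.size - t) * _LOG2PI
            )
            return llf, cf, ViX, XtViX, Py

        theta = _mats_to_theta(H0, R0)
        H, R = _theta_to_mats(theta, t)
        llf, cf, ViX, XtViX, Py = llf_parts(H, R)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            Vinv = sla.cho_solve(cf, np.eye(y.size))
            P_of = lambda v: sla.cho_solve(cf, v) - ViX @ sla.solve(
                XtViX, ViX.T @ v, assume_a="pos"
            )
            grad = np.empty(npar)
            Us = np.empty((y.size, npar))
            for k in range(npar):
                Vd = dV(k)
                tr_pvd = float(np.sum(Vinv * Vd)) - float(
                    np.trace(sla.solve(XtViX, ViX.T @ Vd @ ViX, assume_a="pos"))
                )
                u = Vd @ Py
                Us[:, k] = u
                grad[k] = -0.5 * (tr_pvd - float(Py @ u))
            PU = np.column_stack([P_of(Us[:, k]) for k in range(npar)])
            AI = 0.5 * (Us.T @ PU)
            try:
                step = sla.solve(AI, grad, assume_a="pos")
            except np.linalg.LinAlgError:
                step = sla.lstsq(AI, grad)[0]
            # step-halving: stay in the parameter space and never let the
            # log-likelihood decrease across accepted iterations
            scale = 1.0
            accepted = False
            for _ in range(30):
                cand = theta + scale * step
                Hc, Rc = _theta_to_mats(cand, t)
                if _is_pd(Hc) and _is_pd(Rc):
                    try:
                        new = llf_parts(Hc, Rc)
                    except np.linalg.LinAlgError:
                        new = None
                    if new is not None and new[0] >= llf - 1e-10:
                        accepted = True
                        break
                scale *= 0.5
            if not accepted:
                break
            rel_change = np.max(
                np.abs(scale * step) / (np.abs(theta) + 1e-8)
            )
            theta = cand
            H, R = Hc, Rc
            llf, cf, ViX, XtViX, Py = new
            if rel_change < xtol or np.linalg.norm(grad) < gtol:
                converged = True
                break
        if not converged:
            warnings.warn("AI-REML did not converge", RuntimeWarning)
        return VarianceComponents(
            H=H,
            R=R,
            converged=converged,
            log_likelihood=float(llf),
            iterations=it,
            method="ai",
        )

    def _reml_em(self, H0, R0, maxiter, xtol) -> VarianceComponents:
        for tr, _ in self._patterns:
            if tr.size != self.t:
                raise ModelError("EM requires complete trait patterns")
        if self.n_eq > 6000:
            raise ModelError("EM needs a dense MME inverse; problem too large")
        t, p, q = self.t, self.t, self.q
        H, R = H0.copy(), R0.copy()
        llf_prev = -np.inf
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            C, rhs, yry, extra = self._assemble(H, R)
            Cd = C.toarray() if sp.issparse(C) else C
            Cinv = sla.inv(Cd)
            sol = Cinv @ rhs
            ghat = sol[p:].reshape(q, t)
            mu = sol[:p]
            kinv, _ = self.kinship.precision()
            kinv_d = kinv.toarray() if sp.issparse(kinv) else np.asarray(kinv)
            Cgg = Cinv[p:, p:].reshape(q, t, q, t)
            Hn = np.empty((t, t))
            for a in range(t):
                for b in range(t):
                    Hn[a, b] = (
                        ghat[:, a] @ kinv_d @ ghat[:, b]
                        + np.sum(kinv_d * Cgg[:, a, :, b].T)
                    ) / q
            resid = self.Y - mu - ghat[self.unit_animal]
            Rn = resid.T @ resid
            # PEC of (mu_a + g_{u,a}): W has two unit entries per row, so
            # W Cinv W' is a four-term sum of Cinv entries
            ga = p + self.unit_animal[:, None] * t + np.arange(t)[None, :]
            for a in range(t):
                for b in range(t):
                    Rn[a, b] += (
                        self.n_units * Cinv[a, b]
                        + Cinv[a, ga[:, b]].sum()
                        + Cinv[ga[:, a], b].sum()
                        + Cinv[ga[:, a], ga[:, b]].sum()
                    )
            Rn /= self.n_units
            change = max(
                np.max(np.abs(Hn - H)) / (np.max(np.abs(H)) + 1e-8),
                np.max(np.abs(Rn - R)) / (np.max(np.abs(R)) + 1e-8),
            )
            H, R = 0.5 * (Hn + Hn.T), 0.5 * (Rn + Rn.T)
            if change < max(xtol, 1e-7):
                converged = True
                break
        llf = self.loglike((H, R))
        return VarianceComponents(
            H=H, R=R, converged=converged, log_likelihood=float(llf),
            iterations=it, method="em",
        )


class AnimalModelResults:
    """Fitted animal model: intercepts, genetic-value solutions, variance
    components, reliabilities and a text summary."""

    def __init__(self, model, varcomp, intercepts, solutions, _factor=None):
        self.model = model
        self.varcomp = varcomp
        self.intercepts = intercepts
        self._solutions = solutions
        self._factor = _factor

    @property
    def llf(self) -> float:
        return self.varcomp.log_likelihood

    @property
    def converged(self) -> bool:
        return self.varcomp.converged

    @property
    def model_tag(self) -> str:
        kind = "pedigree" if self.model._sparse else "genomic"
        return ("ST" if self.model.t == 1 else "MT") + "-" + kind

    @property
    def solutions(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._solutions, index=self.model.kinship.ids, columns=self.model.traits
        )

    def predict(self, ids) -> pd.DataFrame:
        pos = self.model.kinship.positions(ids)
        return pd.DataFrame(
            self._solutions[pos], index=np.asarray(ids), columns=self.model.traits
        )

    def prediction_error_variance(self, ids) -> np.ndarray:
        """PEV per (animal, trait): diagonal of the inverted MME coefficient
        matrix at the animal's genetic-effect rows."""
        if self._factor is None or self.model.n_eq > self.model.pev_limit:
            raise ModelError(
                "coefficient-matrix inverse unavailable at this scale; "
                "use the empirical reliability variant"
            )
        pos = self.model.kinship.positions(ids)
        t, p = self.model.t, self.model.t
        idx = (p + pos[:, None] * t + np.arange(t)[None, :]).ravel()
        e = np.zeros((self.model.n_eq, idx.size))
        e[idx, np.arange(idx.size)] = 1.0
        cols = self.model._solve_factor(self._factor, e)
        return cols[idx, np.arange(idx.size)].reshape(len(pos), t)

    def reliability(self, ids=None, kind: str = "pev") -> pd.DataFrame:
        """Reliability r^2 = 1 - PEV / (sigma_g^2 (1 + F)) per animal/trait,
        clamped to [0, 1]."""
        if kind != "pev":
            raise ModelError(
                "only the PEV-based variant lives here; empirical "
                "reliability (squared correlation with TBV) is "
                "mtgblup.evaluate.reliability"
            )
        if ids is None:
            ids = self.model.kinship.ids
        pev = self.prediction_error_variance(ids)
        pos = self.model.kinship.positions(ids)
        f = self.model.kinship.inbreeding_of(pos)
        denom = np.diag(self.varcomp.H)[None, :] * (1.0 + f[:, None])
        rel = 1.0 - pev / denom
        return pd.DataFrame(
            np.clip(rel, 0.0, 1.0), index=np.asarray(ids), columns=self.model.traits
        )

    def summary(self) -> str:
        vc = self.varcomp
        lines = [
            f"Animal model [{self.model_tag}]",
            f"  animals in K: {self.model.q}   record units: {self.model.n_units}"
            f"   observations: {self.model.n_obs}",
            f"  REML method: {vc.method}   converged: {vc.converged}"
            f"   iterations: {vc.iterations}",
            f"  restricted log-likelihood: {vc.log_likelihood:.4f}",
            "  genetic covariance H:",
        ]
        for row in vc.H:
            lines.append("    " + "  ".join(f"{v:10.5f}" for v in row))
        lines.append("  residual covariance R:")
        for row in vc.R:
            lines.append("    " + "  ".join(f"{v:10.5f}" for v in row))
        h2 = vc.heritabilities
        lines.append(
            "  heritabilities: " + "  ".join(f"{v:.4f}" for v in h2)
        )
        if self.model.t == 2:
            lines.append(f"  genetic correlation: {vc.genetic_correlation:.4f}")
        lines.append("  intercepts: " + "  ".join(f"{v:.5f}" for v in self.intercepts))
        return "\n".join(lines)
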