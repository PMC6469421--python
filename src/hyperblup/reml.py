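"""Linear mixed model engine: Henderson's equations + AI-REML.

The model is ``y = X b + sum_m Z_m u_m + e`` with ``u_m ~ N(0, s2_m I)`` and
``e ~ N(0, s2_e I)``.  Arbitrary PSD covariance kernels enter by factoring
``C = U D U'`` and passing ``Z = U D^{1/2}``, which reduces every term to the
iid form above.

Variance components are estimated by average-information REML with EM
fallback steps whenever an AI update leaves the parameter space or lowers
the restricted likelihood.  All per-iteration quantities (solutions, traces,
scores, AI matrix) are computed from the mixed-model equations, so the cost
per iteration is O((p+q)^3) rather than O(n^3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger("hyperblup")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class MixedModelResults:
    """Estimates from one REML (or fixed-variance BLUP) fit."""

    beta: np.ndarray
    u: dict[str, np.ndarray]
    variances: dict[str, float]        # per random term + "residual"
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    beta_cov: np.ndarray | None = None
    boundary: list[str] = field(default_factory=list)

    @property
    def fitted(self) -> np.ndarray:  # set by the engine
        return self._fitted

    def summary(self) -> str:
        lines = ["Mixed model fit (REML)", "-" * 40]
        lines.append(f"observations: {self.n_obs}   iterations: {self.n_iter}")
        lines.append(f"converged: {self.converged}   logLik: {self.loglik:.4f}")
        lines.append("variance components:")
        for k, v in self.variances.items():
            flag = "  (boundary)" if k in self.boundary else ""
            lines.append(f"  {k:<24s} {v:>12.6g}{flag}")
        return "\n".join(lines)


class MixedModelEngine:
    """Holds a fixed design (X, Z-blocks) and fits one or many responses.

    Reusing the engine across responses (e.g. the 62 spectral bands of one
    site-year, which share a design) amortises the ``M'M`` cross-products.
    """

    def __init__(self, X: np.ndarray, z_blocks: list[tuple[str, np.ndarray]]):
        X = np.atleast_2d(np.asarray(X, float))
        self.n = X.shape[0]
        self.p = X.shape[1]
        self.names = [name for name, _ in z_blocks]
        self.q_sizes = [Z.shape[1] for _, Z in z_blocks]
        self.q_arr = np.array(self.q_sizes, dtype=float)
        self.q = int(sum(self.q_sizes))
        self.X = X
        self.M = np.hstack([X] + [np.asarray(Z, float) for _, Z in z_blocks]) if z_blocks else X
        self.MtM = self.M.T @ self.M
        # slices of the u-part of the MME solution vector
        self.slices = []
        off = self.p
        for qm in self.q_sizes:
            self.slices.append(slice(off, off + qm))
            off += qm
        if np.linalg.matrix_rank(X) < self.p:
            raise ValueError("fixed-effect design X is rank deficient")

    # -- core linear algebra ------------------------------------------------

    def _factor(self, variances: np.ndarray, s2e: float):
        lhs = self.MtM.copy()
        for sl, s2m in zip(self.slices, variances):
            lam = s2e / s2m
            lhs[sl, sl] += np.eye(sl.stop - sl.start) * lam
        return cho_factor(lhs, lower=True)

    def _solve(self, fac, v: np.ndarray) -> np.ndarray:
        return cho_solve(fac, self.M.T @ v)

    def _loglik(self, fac, y, theta_hat, variances, s2e) -> float:
        ypy = float(y @ y - theta_hat @ (self.M.T @ y)) / s2e
        logdet_lhs = 2.0 * np.sum(np.log(np.diag(fac[0])))
        ll = -0.5 * (
            (self.n - self.p - self.q) * np.log(s2e)
            + sum(qm * np.log(s2m) for qm, s2m in zip(self.q_sizes, variances))
            + logdet_lhs
            + ypy
        )
        return ll

    # -- public fitting API -------------------------------------------------

    def solve_blup(self, y: np.ndarray, variances: dict[str, float]) -> MixedModelResults:
        """BLUE/BLUP at fixed, user-supplied variance components."""
        var_vec = np.array([variances[n] for n in self.names], float)
        s2e = float(variances["residual"])
        fac = self._factor(var_vec, s2e)
        theta = self._solve(fac, y)
        return self._package(y, fac, theta, var_vec, s2e, loglik=self._loglik(fac, y, theta, var_vec, s2e),
                             converged=True, n_iter=0)

    def fit(
        self,
        y: np.ndarray,
        start: dict[str, float] | None = None,
        max_iter: int = 100,
        tol_ll: float = 1e-8,
        tol_theta: float = 1e-6,
        strict: bool = False,
    ) -> MixedModelResults:
        y = np.asarray(y, float)
        M_terms = len(self.names)
        vy = float(np.var(y)) if self.n > 1 else 1.0
        vy = max(vy, 1e-12)
        floor = 1e-8 * vy

        if M_terms == 0 or self.n - self.p <= 0:
            # no estimable variance structure: OLS fallback
            if self.n - self.p <= 0 and M_terms:
                logger.warning("no residual degrees of freedom; falling back to OLS fixed effects")
            beta, *_ = np.linalg.lstsq(self.X, y, rcond=None)
            res = MixedModelResults(
                beta=beta, u={n: np.zeros(q) for n, q in zip(self.names, self.q_sizes)},
                variances={**{n: 0.0 for n in self.names}, "residual": float(np.var(y - self.X @ beta))},
                loglik=np.nan, converged=True, n_iter=0, n_obs=self.n,
            )
            res._fitted = self.X @ beta
            return res

        if start is not None:
            theta_var = np.array([max(start[n], floor) for n in self.names])
            s2e = max(start["residual"], floor)
        else:
            share = vy / (M_terms + 1)
            theta_var = np.full(M_terms, share)
            s2e = share

        converged = False
        boundary: list[str] = []
        it = 0
        fac = self._factor(theta_var, s2e)
        theta_hat = self._solve(fac, y)
        ll = self._loglik(fac, y, theta_hat, theta_var, s2e)
        for it in range(1, max_iter + 1):
            e = y - self.M @ theta_hat
            ete = float(e @ e)

            # traces of the u-blocks of the inverse coefficient matrix
            inv = cho_solve(fac, np.eye(self.p + self.q))
            tr_cmm = np.array([np.trace(inv[sl, sl]) for sl in self.slices])

            u_norm2 = np.array([float(theta_hat[sl] @ theta_hat[sl]) for sl in self.slices])
            tr_pc = self.q_arr / theta_var - s2e * tr_cmm / theta_var**2
            tr_p = (self.n - self.p - float(tr_pc @ theta_var)) / s2e

            score = np.empty(M_terms + 1)
            score[:M_terms] = -0.5 * (tr_pc - u_norm2 / theta_var**2)
            score[M_terms] = -0.5 * (tr_p - ete / s2e**2)

            cur = np.append(theta_var, s2e)
            # components pinned at the zero boundary with a negative score are
            # fixed there and excluded from the update (ASReml-style)
            pinned = np.zeros(M_terms + 1, bool)
            pinned[:M_terms] = (theta_var <= floor * 1.01) & (score[:M_terms] < 0)
            active = ~pinned

            candidates = []
            ai_dir = self._ai_direction(
                y, fac, theta_hat, theta_var, s2e, e, score, active
            )
            ceil = 1e3 * vy  # guards against drift along flat likelihood ridges
            if ai_dir is not None:
                # project onto the box so single components can hit zero
                for damp in (1.0, 0.5, 0.1):
                    cand = cur.copy()
                    cand[active] = np.clip(cur[active] + damp * ai_dir, floor, ceil)
                    candidates.append(cand)
            # EM step: guaranteed ascent, always available as fallback
            yty_term = float(y @ y - theta_hat @ (self.M.T @ y))
            em_var = (u_norm2 + s2e * tr_cmm) / np.array(self.q_sizes)
            em = np.append(np.maximum(em_var, floor), max(yty_term / (self.n - self.p), floor))
            em[pinned] = floor
            candidates.append(em)

            new = best_ll = best = None
            for cand in candidates:
                if (cand < floor).any() or not np.isfinite(cand).all():
                    continue
                fac_c = self._factor(cand[:M_terms], cand[M_terms])
                th_c = self._solve(fac_c, y)
                ll_c = self._loglik(fac_c, y, th_c, cand[:M_terms], cand[M_terms])
                if best_ll is None or ll_c > best_ll:
                    best_ll, best = ll_c, (cand, fac_c, th_c)
                if ll_c >= ll - 1e-10:
                    new = (cand, fac_c, th_c, ll_c)
                    break
            if new is None:
                # accept the least-bad candidate (EM at worst)
                cand, fac_c, th_c = best
                new = (cand, fac_c, th_c, best_ll)

            cand, fac, theta_hat, ll_new = new
            delta = np.abs(cand - cur).max()
            theta_var, s2e = cand[:M_terms], cand[M_terms]
            improved = ll_new - ll
            ll = ll_new
            if abs(improved) < tol_ll * (1.0 + abs(ll)) and delta < tol_theta * max(vy, 1.0):
                converged = True
                break

        if not converged:
            msg = f"REML did not converge in {max_iter} iterations"
            if strict:
                raise ConvergenceError(msg)
            logger.warning(msg)

        boundary = [n for n, v in zip(self.names, theta_var) if v <= floor * 1.01]
        for b in boundary:
            logger.info("variance component %r pinned at the zero boundary", b)

        fac = self._factor(theta_var, s2e)
        theta_hat = self._solve(fac, y)
        ll = self._loglik(fac, y, theta_hat, theta_var, s2e)
        return self._package(y, fac, theta_hat, theta_var, s2e, ll, converged, it, boundary)

    def _ai_direction(self, y, fac, theta_hat, theta_var, s2e, e, score, active=None):
        """Average-information Newton direction for the active components."""
        M_terms = len(self.names)
        if active is None:
            active = np.ones(M_terms + 1, bool)
        V = np.empty((self.n, M_terms + 1))
        for m, sl in enumerate(self.slices):
            # C_m P y = Z_m u_hat_m / s2_m
            V[:, m] = self.M[:, sl] @ theta_hat[sl] / theta_var[m]
        V[:, M_terms] = e / s2e
        V = V[:, active]
        theta_v = cho_solve(fac, self.M.T @ V)
        PV = (V - self.M @ theta_v) / s2e
        AI = 0.5 * (V.T @ PV)
        AI = 0.5 * (AI + AI.T)
        try:
            return np.linalg.solve(AI + 1e-12 * np.eye(AI.shape[0]), score[active])
        except np.linalg.LinAlgError:
            return None

    def _package(self, y, fac, theta_hat, theta_var, s2e, loglik, converged, n_iter, boundary=()):
        beta = theta_hat[: self.p]
        u = {n: theta_hat[sl].copy() for n, sl in zip(self.names, self.slices)}
        variances = {n: float(v) for n, v in zip(self.names, theta_var)}
        variances["residual"] = float(s2e)
        inv = cho_solve(fac, np.eye(self.p + self.q))
        res = MixedModelResults(
            beta=beta, u=u, variances=variances, loglik=float(loglik),
            converged=converged, n_iter=n_iter, n_obs=self.n,
            beta_cov=s2e * inv[: self.p, : self.p], boundary=list(boundary),
        )
        res._fitted = self.M @ theta_hat
        return res


def solve_mme_dense(
    y: np.ndarray,
    X: np.ndarray,
    z_blocks: list[tuple[str, np.ndarray]],
    variances: dict[str, float],
) -> MixedModelResults:
    """One-shot Henderson solve at fixed variances (convenience wrapper)."""
    return MixedModelEngine(X, z_blocks).solve_blup(np.asarray(y, float), variances)


def kernel_design(C: np.ndarray, eig_tol: float = 1e-10) -> np.ndarray:
    """Factor a PSD kernel as Z Z' = C via truncated eigendecomposition.

    Eigenvalues below ``eig_tol`` (relative to the largest) are discarded, so
    rank-deficient kernels (e.g. spectral H blocks with nbands << n) yield a
    thin Z.
    """
    C = np.asarray(C, float)
    w, U = np.linalg.eigh(0.5 * (C + C.T))
    cutoff = eig_tol * max(w.max(), 1.0)
    keep = w > cutoff
    if not keep.any():
        return np.zeros((C.shape[0], 1))
    return U[:, keep] * np.sqrt(w[keep])
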