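"""Multi-kernel GBLUP over site-year x genotype records.

The response is the vector of per-site-year grain-yield BLUEs.  Fixed
effects are an intercept plus site-year means; each random term contributes
a record-level covariance ``s2_m C_m`` built from a relationship matrix
(genomic G, pedigree A, or spectral H) expanded in "main", "gxe"
(Hadamard with the site-year indicator) or "block_h" (block-diagonal
per-site-year H) mode.

Two estimation back ends are provided.  The default is a blocked Gibbs
sampler in the eigenbasis of each kernel (scaled-inverse-chi-square variance
updates, missing responses imputed each sweep), mirroring the Bayesian GBLUP
samplers used for this model family.  The alternative is AI/EM-REML on the
training records with BLUP prediction from Henderson's equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CoverageError, RecordIndex
from .kernels import expand_kernel
from .reml import MixedModelEngine

logger = logging.getLogger("hyperblup")

VARIANCE_SYMBOLS = {
    ("G", "main"): "sigma2_g",
    ("A", "main"): "sigma2_g",
    ("G", "gxe"): "sigma2_gE",
    ("A", "gxe"): "sigma2_gE",
    ("H", "block_h"): "sigma2_h",
    ("H", "block_h_gxe"): "sigma2_hE",
}


@dataclass
class KernelTerm:
    """One random term: a named record-level covariance matrix."""

    name: str
    source: str          # "G" | "A" | "H"
    mode: str            # "main" | "gxe" | "block_h"
    cov: np.ndarray
    _eig: tuple | None = field(default=None, repr=False)

    def eig(self, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
        """Cached truncated eigendecomposition (U, d) with C ~= U diag(d) U'."""
        if self._eig is None:
            C = 0.5 * (self.cov + self.cov.T)
            w, U = np.linalg.eigh(C)
            scale = max(abs(w).max(), 1.0)
            if w.min() < -1e-6 * scale:
                raise ValueError(
                    f"kernel {self.name!r} is not PSD (min eigenvalue {w.min():.3e})"
                )
            keep = w > tol * scale
            self._eig = (U[:, keep], w[keep])
        return self._eig


@dataclass
class GibbsSettings:
    iterations: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 1234


@dataclass
class RemlSettings:
    max_iter: int = 100
    tol_ll: float = 1e-8
    tol_theta: float = 1e-6


@dataclass
class GblupSpec:
    """A fully assembled prediction model over a record index."""

    idx: RecordIndex
    y: np.ndarray            # response per record, NaN = to be predicted
    X: np.ndarray            # fixed design (intercept [+ site-year effects])
    terms: list[KernelTerm]
    model_name: str = ""

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        if len(self.terms) < 1:
            raise ValueError("a GBLUP spec needs at least one kernel term")
        n = self.idx.n_records
        for t in self.terms:
            if t.cov.shape != (n, n):
                raise ValueError(f"kernel {t.name!r} dimension mismatch with records")
        if self.y.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("response/design length mismatch with records")

    @property
    def train_mask(self) -> np.ndarray:
        return ~np.isnan(self.y)


def _fixed_design(idx: RecordIndex) -> np.ndarray:
    """Intercept plus drop-first site-year effects (omitted if single site-year)."""
    n = idx.n_records
    n_sy = len(idx.site_years)
    if n_sy <= 1:
        return np.ones((n, 1))
    X = np.ones((n, n_sy))
    for j in range(1, n_sy):
        X[:, j] = (idx.site_year_of == j).astype(float)
    return X


def assemble_model(
    model_name: str,
    kernels: dict,
    idx: RecordIndex,
    y: np.ndarray | None = None,
) -> GblupSpec:
    """Build a GblupSpec from a model-battery name.

    ``model_name`` follows the battery vocabulary: single-kernel "G", "A",
    "H.VEG"/"H.HEAD"/"H.GF"/"H.ALL" (or "H.<date>"); multi-kernel
    "G+G_GxE", "A+A_GxE", "G+H.ALL_GxE", etc.  ``kernels`` maps "G"/"A" to
    genotype-level RelationshipMatrix objects and "H" to
    ``{scope: {site_year: RelationshipMatrix}}``.
    """
    terms: list[KernelTerm] = []
    for i, token in enumerate(model_name.split("+")):
        token = token.strip()
        is_gxe = token.endswith("_GxE")
        base = token[: -len("_GxE")] if is_gxe else token
        if base in ("G", "A"):
            if base not in kernels:
                raise CoverageError(f"relationship matrix {base!r} not available")
            mode = "gxe" if is_gxe else "main"
            cov = expand_kernel(kernels[base], idx, mode)
            terms.append(KernelTerm(name=token, source=base, mode=mode, cov=cov))
        elif base.startswith("H."):
            scope = base[2:]
            h_map = kernels.get("H", {})
            if scope not in h_map:
                raise CoverageError(f"no H matrices for scope {scope!r}")
            cov = expand_kernel(h_map[scope], idx, "block_h")
            terms.append(KernelTerm(name=token, source="H", mode="block_h", cov=cov))
        else:
            raise ValueError(f"cannot parse model term {token!r} in {model_name!r}")
    if y is None:
        y = np.full(idx.n_records, np.nan)
    return GblupSpec(idx=idx, y=y, X=_fixed_design(idx), terms=terms, model_name=model_name)


@dataclass
class GblupFit:
    """Variance components and record-level predictions from one model fit."""

    model_name: str
    method: str
    variances: dict[str, float]       # per term + "residual"
    yhat: np.ndarray                  # systematic part for every record
    mc_se: dict[str, float] | None
    n_train: int
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Multi-kernel GBLUP fit: {self.model_name or '(unnamed)'}", "-" * 44]
        lines.append(f"method: {self.method}   training records: {self.n_train}")
        lines.append("variance components:")
        for k, v in self.variances.items():
            se = f"  (MCse {self.mc_se[k]:.3g})" if self.mc_se and k in self.mc_se else ""
            lines.append(f"  {k:<20s} {v:>12.6g}{se}")
        return "\n".join(lines)


class MultiKernelGBLUP:
    """statsmodels-style model object wrapping a GblupSpec."""

    def __init__(self, spec: GblupSpec):
        self.spec = spec

    @classmethod
    def from_kernels(cls, model_name, kernels, idx, y):
        return cls(assemble_model(model_name, kernels, idx, y=y))

    def fit(
        self,
        method: str = "gibbs",
        settings: GibbsSettings | RemlSettings | None = None,
        fixed_variances: dict[str, float] | None = None,
    ) -> GblupFit:
        if method == "gibbs":
            return _fit_gibbs(self.spec, settings or GibbsSettings())
        if method == "em_reml":
            return _fit_reml(self.spec, settings or RemlSettings(), fixed_variances)
        raise ValueError(f"unknown method {method!r}")


def fit_gblup(
    spec: GblupSpec,
    method: str = "gibbs",
    settings=None,
    fixed_variances=None,
) -> GblupFit:
    return MultiKernelGBLUP(spec).fit(method=method, settings=settings,
                                      fixed_variances=fixed_variances)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _fit_gibbs(spec: GblupSpec, st: GibbsSettings) -> GblupFit:
    rng = np.random.default_rng(st.seed)
    y = spec.y.copy()
    obs = spec.train_mask
    n = len(y)
    n_train = int(obs.sum())
    if n_train < 2:
        raise ValueError("need at least 2 training records")
    X = spec.X
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    L_beta = np.linalg.cholesky(XtX_inv)

    eigs = [t.eig() for t in spec.terms]
    M = len(spec.terms)
    vary = float(np.var(y[obs]))
    vary = max(vary, 1e-10)
    df0 = 5.0
    # prior mode of every variance = vary / (M + 1); mode = df*S/(df+2)
    S0 = (vary / (M + 1)) * (df0 + 2.0) / df0

    beta = np.linalg.lstsq(X[obs], y[obs], rcond=None)[0]
    a = [np.zeros(d.shape[0]) for _, d in eigs]
    s2 = np.full(M, vary / (M + 1))
    s2e = vary / (M + 1)
    y[~obs] = (X @ beta)[~obs]

    systematic = X @ beta  # running systematic part X b + sum U a
    yhat_acc = np.zeros(n)
    var_acc = np.zeros(M + 1)
    var_sq_acc = np.zeros(M + 1)
    n_samp = 0

    for sweep in range(st.iterations):
        # fixed effects
        r = y - (systematic - X @ beta)
        mean_b = XtX_inv @ (X.T @ r)
        beta = mean_b + np.sqrt(s2e) * (L_beta @ rng.standard_normal(len(beta)))
        systematic = X @ beta
        for m, (U, d) in enumerate(eigs):
            systematic += U @ a[m]

        # kernel effects, one block at a time, in the eigenbasis
        for m, (U, d) in enumerate(eigs):
            if d.size == 0:
                s2[m] = (df0 * S0) / rng.chisquare(df0)
                continue
            w_old = U @ a[m]
            r = y - systematic + w_old
            t = U.T @ r
            var_j = 1.0 / (1.0 / s2e + 1.0 / (s2[m] * d))
            a[m] = var_j * t / s2e + np.sqrt(var_j) * rng.standard_normal(d.size)
            w_new = U @ a[m]
            systematic += w_new - w_old
            ss = float(np.sum(a[m] ** 2 / d))
            s2[m] = (ss + df0 * S0) / rng.chisquare(df0 + d.size)

        # residual variance and missing-response imputation
        e = y - systematic
        s2e = (float(e @ e) + df0 * S0) / rng.chisquare(df0 + n)
        if not np.isfinite(s2e) or not np.isfinite(systematic).all():
            raise RuntimeError(f"Gibbs sampler diverged at iteration {sweep}")
        y[~obs] = systematic[~obs] + np.sqrt(s2e) * rng.standard_normal((~obs).sum())

        if sweep >= st.burn_in and (sweep - st.burn_in) % st.thin == 0:
            yhat_acc += systematic
            draws = np.append(s2, s2e)
            var_acc += draws
            var_sq_acc += draws**2
            n_samp += 1

    if n_samp == 0:
        raise ValueError("sampler settings leave no post-burn-in samples")
    post_var = var_acc / n_samp
    post_sd = np.sqrt(np.maximum(var_sq_acc / n_samp - post_var**2, 0.0))
    names = [t.name for t in spec.terms] + ["residual"]
    return GblupFit(
        model_name=spec.model_name,
        method="gibbs",
        variances=dict(zip(names, post_var)),
        yhat=yhat_acc / n_samp,
        mc_se={k: float(s / np.sqrt(n_samp)) for k, s in zip(names, post_sd)},
        n_train=n_train,
        diagnostics={"n_samples": n_samp, "posterior_sd": dict(zip(names, post_sd))},
    )


# ---------------------------------------------------------------------------
# REML back end
# ---------------------------------------------------------------------------

def _fit_reml(spec: GblupSpec, st: RemlSettings, fixed_variances=None) -> GblupFit:
    obs = spec.train_mask
    n_train = int(obs.sum())
    if n_train < 2:
        raise ValueError("need at least 2 training records")
    Z_full = []
    for t in spec.terms:
        U, d = t.eig()
        Z_full.append(U * np.sqrt(d) if d.size else np.zeros((len(spec.y), 1)))
    engine = MixedModelEngine(
        spec.X[obs], [(t.name, Z[obs]) for t, Z in zip(spec.terms, Z_full)]
    )
    if fixed_variances is not None:
        res = engine.solve_blup(spec.y[obs], fixed_variances)
    else:
        res = engine.fit(spec.y[obs], max_iter=st.max_iter,
                         tol_ll=st.tol_ll, tol_theta=st.tol_theta)
    yhat = spec.X @ res.beta
    for t, Z in zip(spec.terms, Z_full):
        yhat += Z @ res.u[t.name]
    return GblupFit(
        model_name=spec.model_name,
        method="em_reml",
        variances=res.variances,
        yhat=yhat,
        mc_se=None,
        n_train=n_train,
        converged=res.converged,
        diagnostics={"loglik": res.loglik, "n_iter": res.n_iter},
    )


def predict_masked(fit: GblupFit, idx: RecordIndex) -> pd.DataFrame:
    """Tidy prediction table: one row per record (training rows included)."""
    return pd.DataFrame(
        {
            "site_year": idx.records["site_year"],
            "line_id": idx.records["line_id"],
            "yhat": fit.yhat,
        }
    )
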