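"""Stage one of the pipeline: plot-level mixed models within a site-year.

Grain yield and each hyperspectral band are adjusted for the alpha-lattice
design (random trials, replicates-in-trials, incomplete blocks-in-replicates)
to produce per-line BLUEs (genotype fixed) or BLUPs (genotype random).  Band
adjusted means can be computed per phenotyping date or pooled across the
dates of a developmental growth stage, in which case the date enters as an
extra random effect and the design factors are nested within it.

Growth stages are defined by the phenology of the site-year itself: a date
is vegetative (VEG) while fewer than half of the plots have headed, heading
(HEAD) until all plots have headed, and grain fill (GF) until all plots have
matured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageError, SpectralTable
from .reml import MixedModelEngine, MixedModelResults

logger = logging.getLogger("hyperblup")

STAGES = ("VEG", "HEAD", "GF")


class EmptyScopeError(ValueError):
    """No phenotyping dates fall in the requested scope."""


class ConfigurationError(ValueError):
    pass


@dataclass
class VarianceComponents:
    sigma2_t: float = 0.0
    sigma2_r: float = 0.0
    sigma2_b: float = 0.0
    sigma2_d: float = 0.0
    sigma2_g: float = 0.0
    sigma2_e: float = 0.0

    @classmethod
    def from_variances(cls, variances: dict[str, float]) -> "VarianceComponents":
        key_map = {
            "trial": "sigma2_t",
            "replicate": "sigma2_r",
            "block": "sigma2_b",
            "date": "sigma2_d",
            "genotype": "sigma2_g",
            "residual": "sigma2_e",
        }
        out = cls()
        for name, value in variances.items():
            leaf = name.split(":")[-1]
            setattr(out, key_map.get(leaf, "sigma2_e"), float(value))
        return out


@dataclass
class MixedModelFit:
    """BLUEs or BLUPs for one trait in one site-year, plus variance components."""

    blues: pd.Series | None
    blups: pd.Series | None
    varcomp: VarianceComponents
    results: MixedModelResults
    model_terms: dict

    def summary(self) -> str:
        return self.results.summary()


@dataclass
class BandBlueTable:
    site_year: str
    scope: str                 # a date, a stage name, or "ALL"
    blues: pd.DataFrame        # line x band


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _sum_to_zero(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero dummy coding; the last level is minus the sum of the rest."""
    levels = sorted(labels.unique())
    k = len(levels)
    pos = {g: i for i, g in enumerate(levels)}
    idx = labels.map(pos).to_numpy()
    X = np.zeros((len(labels), k - 1))
    rows = np.arange(len(labels))
    inner = idx < k - 1
    X[rows[inner], idx[inner]] = 1.0
    X[~inner, :] = -1.0
    return X, levels


def _grouping_z(df: pd.DataFrame, cols: tuple[str, ...]) -> np.ndarray:
    labels = df[list(cols)].astype(str).agg("|".join, axis=1)
    codes, uniques = pd.factorize(labels, sort=True)
    Z = np.zeros((len(df), len(uniques)))
    Z[np.arange(len(df)), codes] = 1.0
    return Z


class PlotMixedModel:
    """Model object for the plot-level alpha-lattice mixed model.

    Parameters
    ----------
    data : observation table (one row per plot, or per plot x date)
    response : response column name
    random : grouping factors; each entry is a column name or a tuple of
        column names whose combination defines the factor levels (nesting)
    covariates : numeric fixed covariates (centred before fitting)
    genotype_role : "fixed" yields BLUEs, "random" yields BLUPs
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        random: list,
        covariates: tuple[str, ...] = (),
        genotype: str = "line_id",
        genotype_role: str = "fixed",
    ):
        data = data.loc[data[response].notna()].reset_index(drop=True)
        if len(data) == 0:
            raise ValueError(f"no observations with non-missing {response!r}")
        self.data = data
        self.response = response
        self.genotype_role = genotype_role

        X_parts = [np.ones((len(data), 1))]
        self.levels: list[str] = []
        if genotype_role == "fixed":
            Xg, self.levels = _sum_to_zero(data[genotype])
            X_parts.append(Xg)
        else:
            self.levels = sorted(data[genotype].unique())
        for cov in covariates:
            vals = data[cov].to_numpy(float)
            if np.isnan(vals).any():
                vals = np.where(np.isnan(vals), np.nanmean(vals), vals)
            X_parts.append((vals - vals.mean())[:, None])
        X = np.hstack(X_parts)

        z_blocks: list[tuple[str, np.ndarray]] = []
        if genotype_role == "random":
            Zg = _grouping_z(data, (genotype,))
            z_blocks.append(("genotype", Zg))
        for term in random:
            cols = (term,) if isinstance(term, str) else tuple(term)
            Z = _grouping_z(data, cols)
            if Z.shape[1] < 2:
                # a single-level factor is aliased with the intercept
                logger.info("dropping random term %s: single level", ":".join(cols))
                continue
            z_blocks.append((":".join(cols), Z))
        self.term_names = [n for n, _ in z_blocks]
        self.engine = MixedModelEngine(X, z_blocks)
        self.covariates = covariates

    def fit(self, start=None, **kw) -> MixedModelFit:
        res = self.engine.fit(self.data[self.response].to_numpy(float), start=start, **kw)
        return self._package(res)

    def _package(self, res: MixedModelResults) -> MixedModelFit:
        mu = res.beta[0]
        blues = blups = None
        if self.genotype_role == "fixed":
            k = len(self.levels)
            eff = np.append(res.beta[1:k], -res.beta[1:k].sum())
            blues = pd.Series(mu + eff, index=self.levels, name=self.response)
        else:
            blups = pd.Series(mu + res.u["genotype"], index=self.levels, name=self.response)
        return MixedModelFit(
            blues=blues,
            blups=blups,
            varcomp=VarianceComponents.from_variances(res.variances),
            results=res,
            model_terms={
                "random": self.term_names,
                "covariates": list(self.covariates),
                "genotype_role": self.genotype_role,
            },
        )


def reml_fit(
    records: pd.DataFrame,
    response: str,
    fixed_terms: list | None = None,
    random_terms: list | None = None,
    genotype_role: str = "fixed",
    **kw,
) -> MixedModelFit:
    """Fit a plot-level mixed model by REML (functional surface).

    ``fixed_terms`` are numeric covariate columns; ``random_terms`` are
    grouping factors (column names or tuples for nested labels).
    """
    return PlotMixedModel(
        records,
        response,
        random=random_terms or [],
        covariates=tuple(fixed_terms or ()),
        genotype_role=genotype_role,
    ).fit(**kw)


# ---------------------------------------------------------------------------
# trait BLUEs / BLUPs
# ---------------------------------------------------------------------------

DESIGN_TERMS = ["trial", ("trial", "replicate"), ("trial", "replicate", "block")]


def fit_trait_blues(
    plots: pd.DataFrame,
    trait: str,
    genotype_role: str = "fixed",
    covariates: tuple[str, ...] = (),
    **kw,
) -> MixedModelFit:
    """Per-site-year adjusted means for an agronomic trait.

    Traits scored in a single replicate (DTHD, DTMT) drop the replicate and
    block terms.  A requested lodging covariate is included only when lodging
    was actually observed (> 0 somewhere) in the site-year.
    """
    obs = plots.loc[plots[trait].notna()]
    if obs["line_id"].nunique() < 2:
        raise ValueError(f"trait {trait!r} observed for fewer than 2 lines")
    single_rep = obs["replicate"].nunique() == 1
    random = ["trial"] if single_rep else list(DESIGN_TERMS)
    if single_rep:
        logger.info("%s recorded in one replicate: dropping replicate/block terms", trait)

    covs = []
    for cov in covariates:
        if plots[cov].notna().sum() == 0:
            raise ConfigurationError(f"covariate {cov!r} entirely missing")
        if cov == "lodging" and not (plots[cov].fillna(0) > 0).any():
            logger.info("no lodging observed in site-year: covariate dropped")
            continue
        covs.append(cov)

    model = PlotMixedModel(
        plots, trait, random=random, covariates=tuple(covs), genotype_role=genotype_role
    )
    return model.fit(**kw)


def heritability(sigma2_g: float, sigma2_e: float, nreps: int = 3) -> float:
    """Broad-sense, entry-mean heritability: s2_g / (s2_g + s2_e / nreps)."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValueError("variance components must be non-negative")
    if sigma2_g == 0 and sigma2_e == 0:
        raise ValueError("heritability undefined when both variances are zero")
    return sigma2_g / (sigma2_g + sigma2_e / nreps)


# ---------------------------------------------------------------------------
# growth-stage classification
# ---------------------------------------------------------------------------

def classify_time_points(
    plots: pd.DataFrame,
    dates: list[str],
    sowing_date: str | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Assign VEG/HEAD/GF to each phenotyping date of one site-year.

    Heading/maturity calendar dates are reconstructed as
    ``sowing_date + dthd`` (resp. ``dtmt``) days.  Because phenology is
    scored in a single replicate, coverage and the headed/mature fractions
    are evaluated over lines (one scored plot per line).  A date is VEG
    while the headed fraction is below 0.5, HEAD while it is in [0.5, 1),
    and GF once every line has headed but not all have matured.
    """
    if sowing_date is None:
        if "sowing_date" in plots.columns and plots["sowing_date"].notna().any():
            sowing_date = str(plots["sowing_date"].dropna().iloc[0])
        else:
            raise ConfigurationError("sowing_date required to classify time-points")
    dthd = plots.groupby("line_id")["dthd"].mean()
    n = len(dthd)
    if n == 0 or dthd.notna().mean() < 0.5:
        raise CoverageError("dthd available for fewer than 50% of lines")
    sow = pd.Timestamp(sowing_date)
    head = sow + pd.to_timedelta(dthd.dropna(), unit="D")
    dtmt = plots.groupby("line_id")["dtmt"].mean().dropna()
    mature = sow + pd.to_timedelta(dtmt, unit="D") if len(dtmt) else None

    rows = []
    for d in sorted(dates):
        ts = pd.Timestamp(d)
        frac_head = float((head <= ts).mean())
        if frac_head < 0.5:
            stage = "VEG"
        elif frac_head < 1.0:
            stage = "HEAD"
        else:
            if mature is None or len(mature) < 0.5 * n:
                raise CoverageError("dtmt needed for the GF boundary is insufficient")
            if float((mature <= ts).mean()) < 1.0:
                stage = "GF"
            elif strict:
                raise ValueError(f"date {d} falls after 100% maturity")
            else:
                logger.warning("date %s after full maturity; labelled GF", d)
                stage = "GF"
        rows.append({"date": d, "stage": stage})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# band BLUEs
# ---------------------------------------------------------------------------

def fit_band_blues(
    plots: pd.DataFrame,
    spectra: SpectralTable,
    scope: str,
    site_year: str | None = None,
    stage_labels: pd.DataFrame | None = None,
    sowing_date: str | None = None,
    **kw,
) -> BandBlueTable:
    """Line x band adjusted means for a date, a growth stage, or ALL dates.

    Single-date scope fits the alpha-lattice model per band; stage/ALL scopes
    add a random time-point effect with the design factors nested in it.
    """
    sy = site_year or (plots["site_year"].iloc[0] if "site_year" in plots.columns else "?")
    joined = spectra.frame.merge(
        plots[[c for c in plots.columns if c not in spectra.band_columns]],
        on="plot_id", how="inner",
    )
    if len(joined) == 0:
        raise CoverageError("no spectral records match the supplied plots")
    all_dates = sorted(joined["date"].unique())

    if scope in STAGES:
        if stage_labels is None:
            stage_labels = classify_time_points(plots, all_dates, sowing_date=sowing_date)
        dates = stage_labels.loc[stage_labels["stage"] == scope, "date"].tolist()
        if not dates:
            raise EmptyScopeError(f"no phenotyping dates in stage {scope} for {sy}")
        pooled = True
    elif scope == "ALL":
        dates = all_dates
        pooled = True
    else:
        if scope not in all_dates:
            raise EmptyScopeError(f"date {scope!r} has no spectral records in {sy}")
        dates = [scope]
        pooled = False

    sub = joined.loc[joined["date"].isin(dates)].reset_index(drop=True)
    if pooled and len(dates) > 1:
        random = [
            "date",
            ("date", "trial"),
            ("date", "trial", "replicate"),
            ("date", "trial", "replicate", "block"),
        ]
    else:
        random = list(DESIGN_TERMS)

    model = PlotMixedModel(sub, spectra.band_columns[0], random=random)
    blues = {}
    start = None
    for band in spectra.band_columns:
        y = sub[band].to_numpy(float)
        res = model.engine.fit(y, start=start, **kw)
        start = res.variances  # warm start: bands have similar structure
        fit = model._package(res)
        blues[band] = fit.blues
    table = pd.DataFrame(blues)
    table.index.name = "line_id"
    return BandBlueTable(site_year=sy, scope=scope, blues=table)
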