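"""End-to-end orchestration: raw tables -> BLUEs -> kernels -> StudyBundle.

This is the stage-wise pipeline: plot-level adjusted means per site-year,
genomic/pedigree/hyperspectral relationship matrices, and the record-level
containers the prediction battery consumes.
"""

from __future__ import annotations

import logging

import pandas as pd

from .evaluation import StudyBundle
from .io import MarkerMatrix, Pedigree, SpectralTable, build_record_index
from .kernels import build_a_matrix, build_g_matrix, build_h_matrix, qc_and_impute_markers
from .simulate import SyntheticDataset
from .stagewise import (
    EmptyScopeError,
    classify_time_points,
    fit_band_blues,
    fit_trait_blues,
    heritability,
)

logger = logging.getLogger("hyperblup")


def site_year_tables(phenotypes: pd.DataFrame):
    for sy, sub in phenotypes.groupby("site_year", sort=True):
        yield sy, sub.reset_index(drop=True)


def _fill_line_dthd(plots: pd.DataFrame) -> pd.DataFrame:
    """Propagate the single-replicate heading score to every plot of a line."""
    plots = plots.copy()
    plots["dthd_line"] = plots.groupby("line_id")["dthd"].transform("mean")
    return plots


def prepare_bundle(
    phenotypes: pd.DataFrame,
    spectra: SpectralTable | None = None,
    markers: MarkerMatrix | None = None,
    pedigree: Pedigree | None = None,
    stages: tuple[str, ...] = ("ALL",),
    founder_inbreeding: float = 0.0,
    **fit_kw,
) -> StudyBundle:
    """Run the stage-wise pipeline and assemble a prediction-ready bundle.

    Produces, per site-year: GY BLUEs (the model response), GY BLUPs with and
    without a heading-date covariate (the two validation variants), and — if
    spectra are supplied — H matrices for each requested scope (growth-stage
    name, "ALL", or a date).  Site-years in which a stage has no phenotyping
    dates simply lack that H block; models needing it are reported absent.
    """
    idx = build_record_index(phenotypes)
    response = {}
    valid_plain: dict[str, float] = {}
    valid_corrected: dict[str, float] = {}
    h_map: dict[str, dict] = {s: {} for s in stages}

    for sy, plots in site_year_tables(phenotypes):
        plots = _fill_line_dthd(plots)
        blue = fit_trait_blues(plots, "gy", genotype_role="fixed",
                               covariates=("lodging",), **fit_kw)
        blup = fit_trait_blues(plots, "gy", genotype_role="random",
                               covariates=("lodging",), **fit_kw)
        blup_c = fit_trait_blues(plots, "gy", genotype_role="random",
                                 covariates=("lodging", "dthd_line"), **fit_kw)
        for line, v in blue.blues.items():
            response[f"{sy}::{line}"] = v
        for line, v in blup.blups.items():
            valid_plain[f"{sy}::{line}"] = v
        for line, v in blup_c.blups.items():
            valid_corrected[f"{sy}::{line}"] = v

        if spectra is not None:
            sy_plots = set(plots["plot_id"])
            spec_sub = SpectralTable(
                frame=spectra.frame.loc[spectra.frame["plot_id"].isin(sy_plots)],
                band_columns=spectra.band_columns,
            )
            if len(spec_sub.frame) == 0:
                logger.warning("no spectral records for site-year %s", sy)
                continue
            dates = sorted(spec_sub.frame["date"].unique())
            labels = classify_time_points(plots, dates)
            for scope in stages:
                try:
                    bbt = fit_band_blues(plots, spec_sub, scope, site_year=sy,
                                         stage_labels=labels, **fit_kw)
                except EmptyScopeError as exc:
                    logger.info("%s", exc)
                    continue
                h_map[scope][sy] = build_h_matrix(bbt.blues)

    kernels: dict = {}
    if markers is not None:
        imputed, report = qc_and_impute_markers(markers)
        kernels["G"] = build_g_matrix(imputed)
    if pedigree is not None:
        kernels["A"] = build_a_matrix(pedigree, founder_inbreeding=founder_inbreeding)
    if spectra is not None:
        kernels["H"] = h_map

    checks = set(phenotypes.loc[phenotypes["is_check"], "line_id"])
    keys = idx.keys()
    return StudyBundle(
        idx=idx,
        response=pd.Series(response).reindex(keys.to_numpy()),
        validation={
            "uncorrected": pd.Series(valid_plain),
            "dthd_corrected": pd.Series(valid_corrected),
        },
        kernels=kernels,
        check_lines=checks,
    )


def bundle_from_dataset(ds: SyntheticDataset, stages=("ALL",), **kw) -> StudyBundle:
    return prepare_bundle(ds.phenotypes, spectra=ds.spectra, markers=ds.markers,
                          pedigree=ds.pedigree, stages=stages, **kw)


def gy_heritabilities(phenotypes: pd.DataFrame, nreps: int = 3) -> pd.Series:
    """Broad-sense entry-mean heritability of grain yield per site-year."""
    out = {}
    for sy, plots in site_year_tables(phenotypes):
        fit = fit_trait_blues(plots, "gy", genotype_role="random")
        out[sy] = heritability(fit.varcomp.sigma2_g, fit.varcomp.sigma2_e, nreps=nreps)
    return pd.Series(out, name="H2")
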