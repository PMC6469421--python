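"""Train-test partition schemes, prediction batteries and accuracy summaries.

Three schemes mirror the testing problems of a multi-environment breeding
program: prediction of unobserved lines within one site-year, prediction of
one managed treatment from the other treatments of the same breeding cycle,
and prediction of a new breeding cycle from earlier cycles of the same
treatment.  Accuracy is the Pearson correlation between model predictions
and grain-yield BLUPs on the test records; the same 20 partitions are reused
for every model so comparisons are paired.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gblup import GblupSpec, GibbsSettings, MultiKernelGBLUP, assemble_model
from .io import CoverageError, RecordIndex

logger = logging.getLogger("hyperblup")

SCHEMES = (
    "within_site_year",
    "within_cycle_across_treatments",
    "across_cycles_within_treatment",
)


class ConfigurationError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class Partition:
    scheme: str
    focal: str               # site-year key, or "cycle/treatment" label
    replicate: int           # 1..n_partitions
    seed: int
    trn: list[str]           # record keys "site_year::line_id"
    tst: list[str]

    def __post_init__(self):
        overlap = set(self.trn) & set(self.tst)
        if overlap:
            raise ValueError(f"TRN/TST overlap: {sorted(overlap)[:3]}")


def _partition_seed(master_seed: int, scheme: str, focal: str, replicate: int) -> int:
    h = zlib.crc32(f"{scheme}|{focal}|{replicate}".encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % (2**31))


def _records_meta(idx: RecordIndex) -> pd.DataFrame:
    meta = idx.records.copy()
    parts = meta["site_year"].str.split("/", n=1, expand=True)
    meta["cycle"] = parts[0]
    meta["treatment"] = parts[1]
    meta["key"] = idx.keys()
    return meta


def focal_units(scheme: str, idx: RecordIndex) -> list[str]:
    meta = _records_meta(idx)
    if scheme == "within_site_year":
        return sorted(meta["site_year"].unique())
    if scheme in ("within_cycle_across_treatments", "across_cycles_within_treatment"):
        return sorted(meta["site_year"].unique())  # focal = one (cycle, treatment)
    raise ConfigurationError(f"unknown scheme {scheme!r}")


def make_partitions(
    scheme: str,
    idx: RecordIndex,
    focal: str,
    n_partitions: int = 20,
    master_seed: int = 0,
    check_lines: set[str] | frozenset[str] = frozenset(),
    trn_fraction: float = 0.8,
) -> list[Partition]:
    """Reproducible TRN/TST splits for one focal unit.

    within_site_year: TRN = floor(trn_fraction * n) records of the focal
    site-year, TST the remainder.  The across-treatment and across-cycle
    schemes put every record of the non-focal treatments (resp. cycles) in
    TRN plus floor(0.2 * n_focal) focal records; the remaining focal records
    form TST.  Check lines are kept in TRN and never sampled into TST.
    """
    meta = _records_meta(idx)
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    if focal not in set(meta["site_year"]):
        raise ConfigurationError(f"focal unit {focal!r} absent from the record index")
    cycle, treatment = focal.split("/", 1)

    if scheme == "within_site_year":
        pool = meta.loc[meta["site_year"] == focal]
        always_trn = pd.DataFrame(columns=meta.columns)
        focal_frac = trn_fraction
    elif scheme == "within_cycle_across_treatments":
        in_cycle = meta.loc[meta["cycle"] == cycle]
        pool = in_cycle.loc[in_cycle["treatment"] == treatment]
        always_trn = in_cycle.loc[in_cycle["treatment"] != treatment]
        focal_frac = 1.0 - trn_fraction
    else:  # across_cycles_within_treatment
        in_treat = meta.loc[meta["treatment"] == treatment]
        pool = in_treat.loc[in_treat["cycle"] == cycle]
        always_trn = in_treat.loc[in_treat["cycle"] != cycle]
        focal_frac = 1.0 - trn_fraction

    if len(pool) < 10:
        raise ConfigurationError(
            f"focal unit {focal!r} has only {len(pool)} records (need >= 10)"
        )
    n_focal_trn = int(np.floor(focal_frac * len(pool) + 1e-9))
    n_tst = len(pool) - n_focal_trn
    eligible = pool.loc[~pool["line_id"].isin(check_lines)]
    if len(eligible) < n_tst:
        raise ConfigurationError("not enough non-check records to fill the TST set")

    out = []
    for rep in range(1, n_partitions + 1):
        seed = _partition_seed(master_seed, scheme, focal, rep)
        rng = np.random.default_rng(seed)
        tst_keys = sorted(rng.choice(eligible["key"].to_numpy(), size=n_tst, replace=False))
        tst_set = set(tst_keys)
        trn_keys = sorted(
            set(pool["key"]) - tst_set | set(always_trn["key"])
        )
        out.append(Partition(scheme=scheme, focal=focal, replicate=rep,
                             seed=seed, trn=trn_keys, tst=tst_keys))
    return out


def accuracy(predictions: pd.Series, validation: pd.Series) -> float:
    """Pearson correlation between predictions and validation BLUPs."""
    joined = pd.concat([predictions, validation], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise UndefinedCorrelationError("fewer than 3 paired records")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything a prediction battery consumes, on a shared record index."""

    idx: RecordIndex
    response: pd.Series                 # GY BLUEs keyed by record key
    validation: dict[str, pd.Series]    # variant -> GY BLUPs by record key
    kernels: dict                       # "G"/"A" matrices, "H": {scope: {sy: H}}
    check_lines: set[str] = field(default_factory=set)


WITHIN_SY_ALLOWED = ("G", "A", "H.")  # single-kernel only; no site-year term


def _scheme_record_mask(scheme: str, focal: str, meta: pd.DataFrame) -> np.ndarray:
    cycle, treatment = focal.split("/", 1)
    if scheme == "within_site_year":
        return (meta["site_year"] == focal).to_numpy()
    if scheme == "within_cycle_across_treatments":
        return (meta["cycle"] == cycle).to_numpy()
    return (meta["treatment"] == treatment).to_numpy()


def run_battery(
    bundle: StudyBundle,
    models: list[str],
    schemes: list[str],
    n_partitions: int = 20,
    master_seed: int = 0,
    method: str = "gibbs",
    settings: GibbsSettings | None = None,
) -> pd.DataFrame:
    """Accuracies for every model x scheme x focal unit x validation variant.

    Returns a tidy frame with one row per partition; failed or inapplicable
    cells are recorded with a reason and NaN accuracy instead of aborting the
    battery.
    """
    meta = _records_meta(bundle.idx)
    rows = []
    for scheme in schemes:
        for focal in focal_units(scheme, bundle.idx):
            mask = _scheme_record_mask(scheme, focal, meta)
            sub_idx = bundle.idx.subset(mask)
            sub_keys = sub_idx.keys()
            y_all = bundle.response.reindex(sub_keys).to_numpy()
            try:
                parts = make_partitions(
                    scheme, bundle.idx, focal, n_partitions=n_partitions,
                    master_seed=master_seed, check_lines=bundle.check_lines,
                )
            except ConfigurationError as exc:
                rows.append(_absent_row(scheme, focal, "*", str(exc)))
                continue
            key_pos = {k: i for i, k in enumerate(sub_keys)}

            for model_name in models:
                if scheme == "within_site_year" and "+" in model_name:
                    rows.append(_absent_row(scheme, focal, model_name,
                                            "multi-kernel models need multiple site-years"))
                    continue
                try:
                    spec = assemble_model(model_name, bundle.kernels, sub_idx,
                                          y=np.full(sub_idx.n_records, np.nan))
                except (CoverageError, ValueError) as exc:
                    rows.append(_absent_row(scheme, focal, model_name, str(exc)))
                    continue
                for part in parts:
                    y = y_all.copy()
                    tst_pos = [key_pos[k] for k in part.tst if k in key_pos]
                    trn_pos = [key_pos[k] for k in part.trn if k in key_pos]
                    keep = np.zeros(len(y), bool)
                    keep[trn_pos] = True
                    y[~keep] = np.nan
                    spec_p = GblupSpec(idx=sub_idx, y=y, X=spec.X,
                                       terms=spec.terms, model_name=model_name)
                    try:
                        fit = MultiKernelGBLUP(spec_p).fit(method=method, settings=settings)
                        preds = pd.Series(fit.yhat[tst_pos],
                                          index=sub_keys.iloc[tst_pos].to_numpy())
                        for variant, blups in bundle.validation.items():
                            try:
                                r = accuracy(preds, blups)
                            except UndefinedCorrelationError as exc:
                                logger.warning("undefined accuracy for %s/%s: %s",
                                               model_name, focal, exc)
                                r = np.nan
                            rows.append({
                                "model": model_name, "scheme": scheme, "focal": focal,
                                "variant": variant, "partition": part.replicate,
                                "r": r, "reason": "",
                            })
                    except Exception as exc:  # partition-level failure: log + continue
                        logger.warning("fit failed (%s, %s, part %d): %s",
                                       model_name, focal, part.replicate, exc)
                        rows.append(_absent_row(scheme, focal, model_name, str(exc),
                                                partition=part.replicate))
    return pd.DataFrame(rows)


def _absent_row(scheme, focal, model, reason, partition=np.nan):
    return {
        "model": model, "scheme": scheme, "focal": focal, "variant": "*",
        "partition": partition, "r": np.nan, "reason": reason,
    }


def summarize_accuracy(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of the per-partition Pearson accuracies."""
    ok = results.loc[results["reason"] == ""]
    return (
        ok.groupby(["model", "scheme", "focal", "variant"])["r"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


# ---------------------------------------------------------------------------
# descriptive correlations
# ---------------------------------------------------------------------------

def band_gy_correlations(band_blues: pd.DataFrame, gy_blues: pd.Series) -> pd.Series:
    """Per-band Pearson correlation between band BLUEs and GY BLUEs."""
    shared = band_blues.index.intersection(gy_blues.dropna().index)
    if len(shared) < 3:
        raise CoverageError("fewer than 3 lines shared between band and GY BLUEs")
    B = band_blues.loc[shared].to_numpy(float)
    g = gy_blues.loc[shared].to_numpy(float)
    Bc = B - B.mean(axis=0)
    gc = g - g.mean()
    denom = np.sqrt((Bc**2).sum(axis=0) * (gc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Bc.T @ gc / denom, np.nan)
    return pd.Series(r, index=band_blues.columns, name="r")


def treatment_gy_correlations(gy_blues_by_treatment: dict[str, pd.Series]) -> pd.DataFrame:
    """Treatment x treatment correlation matrix of GY BLUEs within a cycle."""
    treatments = list(gy_blues_by_treatment)
    out = pd.DataFrame(np.eye(len(treatments)), index=treatments, columns=treatments)
    for i, a in enumerate(treatments):
        for b in treatments[i + 1:]:
            r = accuracy(gy_blues_by_treatment[a], gy_blues_by_treatment[b])
            out.loc[a, b] = out.loc[b, a] = r
    return out
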