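"""Shared data model: typed tables for plots, spectra, markers and pedigrees.

All on-disk formats are long-format CSV with a header row.  Band columns in
spectral tables are named by wavelength, e.g. ``b398``.  Dates are ISO-8601
strings so that lexicographic and chronological order coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hyperblup")

#: managed-treatment vocabulary of the multi-environment wheat trials
DEFAULT_TREATMENTS = (
    "Optimal Bed",
    "Optimal Flat",
    "Moderate Drought",
    "Severe Drought",
    "Heat",
)

PHENOTYPE_COLUMNS = (
    "plot_id",
    "line_id",
    "cycle",
    "treatment",
    "trial",
    "replicate",
    "block",
    "gy",
    "lodging",
    "dthd",
    "dtmt",
)


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class IntegrityError(ValueError):
    """Row-level invariant violated (duplicates, impossible values, cycles)."""


class VocabularyError(ValueError):
    """A label falls outside the configured closed vocabulary."""


class CoverageError(ValueError):
    """An id required by an operation is absent from the supplying table."""


def site_year_key(cycle: str, treatment: str) -> str:
    """Canonical label for a (breeding cycle, managed treatment) combination."""
    return f"{cycle}/{treatment}"


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def load_phenotypes(path, treatments=DEFAULT_TREATMENTS) -> pd.DataFrame:
    """Read and validate the plot-level phenotype table.

    Returns a DataFrame with one row per plot, nullable float columns for the
    agronomic traits and an ``is_check`` flag (all-False when absent from the
    file) plus a ``site_year`` convenience column.
    """
    df = pd.read_csv(path, dtype={"cycle": str, "treatment": str, "line_id": str, "plot_id": str})
    return validate_phenotypes(df, treatments=treatments)


def validate_phenotypes(df: pd.DataFrame, treatments=DEFAULT_TREATMENTS) -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype table missing required columns: {missing}")
    df = df.copy()
    for col in ("plot_id", "line_id", "cycle", "treatment"):
        df[col] = df[col].astype(str)
    for col in ("trial", "replicate", "block"):
        df[col] = df[col].astype(int)
    for col in ("gy", "lodging", "dthd", "dtmt"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "is_check" not in df.columns:
        df["is_check"] = False
    df["is_check"] = df["is_check"].fillna(False).astype(bool)

    if df["plot_id"].duplicated().any():
        dup = df.loc[df["plot_id"].duplicated(), "plot_id"].iloc[0]
        raise IntegrityError(f"duplicate plot_id {dup!r}")
    unknown = set(df["treatment"]) - set(treatments)
    if unknown:
        raise VocabularyError(f"unknown treatment labels: {sorted(unknown)}")
    neg = df["gy"] < 0
    if neg.any():
        raise IntegrityError(f"negative grain yield in plot {df.loc[neg, 'plot_id'].iloc[0]!r}")
    both = df["dthd"].notna() & df["dtmt"].notna()
    bad = both & (df["dtmt"] < df["dthd"])
    if bad.any():
        raise IntegrityError(
            f"dtmt < dthd for plot {df.loc[bad, 'plot_id'].iloc[0]!r}"
        )
    df["site_year"] = [site_year_key(c, t) for c, t in zip(df["cycle"], df["treatment"])]
    logger.info("loaded %d plot records across %d site-years", len(df), df["site_year"].nunique())
    return df


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectralTable:
    """Plot x date hyperspectral reflectances.

    ``frame`` holds one row per (plot_id, date); band columns are named
    ``b<wavelength>`` and listed, in order, in ``band_columns``.
    """

    frame: pd.DataFrame
    band_columns: list[str]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([float(c[1:]) for c in self.band_columns])

    @property
    def nbands(self) -> int:
        return len(self.band_columns)


def load_spectra(path, expected_nbands: int | None = None) -> SpectralTable:
    df = pd.read_csv(path, dtype={"plot_id": str, "date": str})
    return validate_spectra(df, expected_nbands=expected_nbands)


def validate_spectra(df: pd.DataFrame, expected_nbands: int | None = None) -> SpectralTable:
    for col in ("plot_id", "date"):
        if col not in df.columns:
            raise SchemaError(f"spectra table missing required column {col!r}")
    band_cols = [c for c in df.columns if c.startswith("b") and c[1:].replace(".", "", 1).isdigit()]
    if not band_cols:
        raise SchemaError("spectra table has no band columns (expected names like 'b398')")
    if expected_nbands is not None and len(band_cols) != expected_nbands:
        raise SchemaError(
            f"expected {expected_nbands} band columns, found {len(band_cols)}"
        )
    df = df.copy()
    df["plot_id"] = df["plot_id"].astype(str)
    df["date"] = df["date"].astype(str)
    vals = df[band_cols].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise IntegrityError("non-finite reflectance values present")
    dup = df.duplicated(subset=["plot_id", "date"])
    if dup.any():
        key = df.loc[dup, ["plot_id", "date"]].iloc[0].tolist()
        raise IntegrityError(f"duplicate spectral record for (plot, date) = {key}")
    logger.info("loaded %d spectral records, %d bands", len(df), len(band_cols))
    return SpectralTable(frame=df, band_columns=band_cols)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

@dataclass
class MarkerMatrix:
    """Biallelic marker dosages, rows = lines, entries in {0,1,2} or NaN.

    After mean-imputation (``imputed=True``) codes are real numbers in
    [0, 2] and missing values are no longer allowed.
    """

    line_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray  # float, NaN = missing
    imputed: bool = False

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise SchemaError("marker matrix dimensions inconsistent with ids")
        if self.imputed:
            if np.isnan(self.codes).any():
                raise IntegrityError("imputed marker matrix contains missing cells")
            if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 2):
                raise IntegrityError("imputed marker codes must lie in [0, 2]")
            return
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise IntegrityError(f"marker code {bad!r} outside {{0,1,2,missing}}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


def load_markers(path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    return MarkerMatrix(
        line_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        codes=df.to_numpy(dtype=float),
    )


def write_markers(m: MarkerMatrix, path) -> None:
    pd.DataFrame(m.codes, index=m.line_ids, columns=m.marker_ids).to_csv(
        path, index_label="line_id"
    )


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Two-parent pedigree; unknown parents are None.

    ``ordered_ids`` lists every individual parents-before-offspring; building
    it verifies acyclicity and that every named parent is itself an entry or a
    declared founder.
    """

    parents: dict[str, tuple[str | None, str | None]]
    ordered_ids: list[str] = field(init=False)

    def __post_init__(self):
        self.ordered_ids = self._toposort()

    def _toposort(self) -> list[str]:
        known = set(self.parents)
        for child, (p1, p2) in self.parents.items():
            for p in (p1, p2):
                if p is not None and p not in known:
                    raise IntegrityError(
                        f"parent {p!r} of {child!r} is not itself a pedigree entry"
                    )
        order: list[str] = []
        state: dict[str, int] = {}  # 1 = visiting, 2 = done

        for root in self.parents:
            if state.get(root):
                continue
            stack = [(root, iter([p for p in self.parents[root] if p is not None]))]
            state[root] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    s = state.get(p)
                    if s == 1:
                        raise IntegrityError(f"pedigree cycle involving {p!r}")
                    if s is None:
                        state[p] = 1
                        stack.append((p, iter([q for q in self.parents[p] if q is not None])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    order.append(node)
                    stack.pop()
        return order


def load_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    for col in ("line_id", "parent1", "parent2"):
        if col not in df.columns:
            raise SchemaError(f"pedigree table missing required column {col!r}")
    parents = {}
    for _, row in df.iterrows():
        p1 = row["parent1"] if isinstance(row["parent1"], str) and row["parent1"] else None
        p2 = row["parent2"] if isinstance(row["parent2"], str) and row["parent2"] else None
        parents[str(row["line_id"])] = (p1, p2)
    return Pedigree(parents=parents)


def write_pedigree(p: Pedigree, path) -> None:
    rows = [
        {"line_id": k, "parent1": v[0] or "", "parent2": v[1] or ""}
        for k, v in p.parents.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# record index
# ---------------------------------------------------------------------------

@dataclass
class RecordIndex:
    """Ordered (site_year, line_id) response records with incidence maps.

    The multi-environment models operate on one record per distinct
    site-year x genotype combination.  ``genotype_of`` / ``site_year_of``
    map record position -> column of the corresponding incidence matrix.
    """

    records: pd.DataFrame          # columns: site_year, line_id (sorted)
    genotypes: list[str]
    site_years: list[str]
    genotype_of: np.ndarray        # int per record
    site_year_of: np.ndarray       # int per record

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def Z_g(self) -> np.ndarray:
        Z = np.zeros((self.n_records, len(self.genotypes)))
        Z[np.arange(self.n_records), self.genotype_of] = 1.0
        return Z

    @property
    def Z_E(self) -> np.ndarray:
        Z = np.zeros((self.n_records, len(self.site_years)))
        Z[np.arange(self.n_records), self.site_year_of] = 1.0
        return Z

    def keys(self) -> pd.Series:
        return self.records["site_year"] + "::" + self.records["line_id"]

    def subset(self, mask: np.ndarray) -> "RecordIndex":
        """Record index restricted to ``mask`` (order preserved)."""
        rec = self.records.loc[np.asarray(mask)].reset_index(drop=True)
        genotypes = sorted(rec["line_id"].unique())
        site_years = sorted(rec["site_year"].unique())
        g_pos = {g: i for i, g in enumerate(genotypes)}
        e_pos = {e: i for i, e in enumerate(site_years)}
        return RecordIndex(
            records=rec,
            genotypes=genotypes,
            site_years=site_years,
            genotype_of=rec["line_id"].map(g_pos).to_numpy(),
            site_year_of=rec["site_year"].map(e_pos).to_numpy(),
        )


def build_record_index(phenotypes: pd.DataFrame) -> RecordIndex:
    """One record per distinct (site_year, line_id), deterministically sorted."""
    if len(phenotypes) == 0:
        raise IntegrityError("cannot build a record index from an empty table")
    rec = (
        phenotypes[["site_year", "line_id"]]
        .drop_duplicates()
        .sort_values(["site_year", "line_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    genotypes = sorted(rec["line_id"].unique())
    site_years = sorted(rec["site_year"].unique())
    g_pos = {g: i for i, g in enumerate(genotypes)}
    e_pos = {e: i for i, e in enumerate(site_years)}
    return RecordIndex(
        records=rec,
        genotypes=genotypes,
        site_years=site_years,
        genotype_of=rec["line_id"].map(g_pos).to_numpy(),
        site_year_of=rec["site_year"].map(e_pos).to_numpy(),
    )
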