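"""Relationship matrices: genomic (G), pedigree (A) and hyperspectral (H).

G follows VanRaden method 1, ``G = ZZ' / (2 sum p_k (1-p_k))`` with Z the
allele-frequency-centred dosages.  A is the numerator relationship matrix by
the tabular method (twice the coefficient of parentage).  H treats the
per-band adjusted means within a site-year as a high-dimensional phenotype:
``H = SS'/nbands`` with S column-centred and scaled to unit sample variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageError, IntegrityError, MarkerMatrix, Pedigree, RecordIndex

logger = logging.getLogger("hyperblup")


class DegenerateInputError(ValueError):
    """Input leaves the operation undefined (e.g. all markers monomorphic)."""


@dataclass
class MarkerQCReport:
    n_input_markers: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int
    allele_freq: pd.Series  # per retained marker

    def __post_init__(self):
        assert (
            self.n_input_markers
            == self.n_removed_missing + self.n_removed_maf + self.n_retained
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_input_markers": [self.n_input_markers],
                "n_removed_missing": [self.n_removed_missing],
                "n_removed_maf": [self.n_removed_maf],
                "n_retained": [self.n_retained],
            }
        )


@dataclass
class RelationshipMatrix:
    """Symmetric PSD similarity over genotypes (or site-year records)."""

    ids: list[str]
    values: np.ndarray
    kind: str          # "G" | "A" | "H"
    scope: str = "genotype"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape inconsistent with ids")
        if len(set(self.ids)) != n:
            raise ValueError("relationship matrix ids must be unique")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > 1e-10:
            raise ValueError(f"matrix not symmetric (max deviation {asym:.2e})")

    def check_psd(self, tol: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -tol:
            raise ValueError(f"matrix not PSD (min eigenvalue {w.min():.2e})")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, index_label="id"
        )

    @classmethod
    def from_csv(cls, path, kind: str, scope: str = "genotype") -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(float), kind=kind, scope=scope)

    def submatrix(self, ids: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise CoverageError(f"ids absent from {self.kind} matrix: {missing[:5]}")
        idx = np.array([pos[g] for g in ids])
        return self.values[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# marker QC + G
# ---------------------------------------------------------------------------

def qc_and_impute_markers(
    m: MarkerMatrix, max_missing: float = 0.70, min_maf: float = 0.05
) -> tuple[MarkerMatrix, MarkerQCReport]:
    """Filter markers by missingness then MAF; mean-impute the survivors.

    A marker is removed when its share of missing calls exceeds
    ``max_missing``, otherwise when its minor allele frequency (computed on
    observed codes) falls below ``min_maf``.  Remaining missing cells are
    replaced by the column mean of observed dosages.
    """
    codes = m.codes
    n = codes.shape[0]
    miss_share = np.isnan(codes).mean(axis=0)
    fail_missing = miss_share > max_missing

    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    fail_maf = ~fail_missing & ((maf < min_maf) | np.isnan(maf))

    keep = ~fail_missing & ~fail_maf
    if not keep.any():
        raise DegenerateInputError("marker QC removed every marker")

    kept = codes[:, keep].copy()
    col_mean = np.nanmean(kept, axis=0)
    nan_r, nan_c = np.where(np.isnan(kept))
    kept[nan_r, nan_c] = col_mean[nan_c]

    marker_ids = [mid for mid, k in zip(m.marker_ids, keep) if k]
    report = MarkerQCReport(
        n_input_markers=m.n_markers,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
        allele_freq=pd.Series(col_mean / 2.0, index=marker_ids),
    )
    logger.info(
        "marker QC: %d in, %d removed (missing), %d removed (MAF), %d retained",
        report.n_input_markers, report.n_removed_missing,
        report.n_removed_maf, report.n_retained,
    )
    out = MarkerMatrix(
        line_ids=list(m.line_ids), marker_ids=marker_ids, codes=kept, imputed=True
    )
    return out, report


def build_g_matrix(m: MarkerMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from imputed dosages."""
    if m.n_lines < 2 or m.n_markers < 1:
        raise DegenerateInputError("need at least 2 lines and 1 marker for G")
    codes = m.codes
    if np.isnan(codes).any():
        raise IntegrityError("G requires imputed (missing-free) marker codes")
    p = codes.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise DegenerateInputError("all markers monomorphic: VanRaden denominator is 0")
    Z = codes - 2.0 * p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(ids=list(m.line_ids), values=G, kind="G")


# ---------------------------------------------------------------------------
# pedigree A
# ---------------------------------------------------------------------------

def build_a_matrix(p: Pedigree, founder_inbreeding: float = 0.0) -> RelationshipMatrix:
    """Numerator relationship matrix (twice the coefficient of parentage).

    Tabular method over the topologically sorted pedigree: founders get
    diagonal 1 + f0 (f0 = ``founder_inbreeding``; 1.0 for fully inbred
    lines), non-founders A_ii = 1 + 0.5 A_{p1,p2}, off-diagonals
    A_ij = 0.5 (A_{j,p1(i)} + A_{j,p2(i)}) with unknown parents
    contributing 0.
    """
    ids = p.ordered_ids
    pos = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, g in enumerate(ids):
        p1, p2 = p.parents[g]
        i1 = pos[p1] if p1 is not None else None
        i2 = pos[p2] if p2 is not None else None
        if i1 is None and i2 is None:
            A[i, i] = 1.0 + founder_inbreeding
        else:
            A[i, i] = 1.0 + 0.5 * (A[i1, i2] if (i1 is not None and i2 is not None) else 0.0)
        for j in range(i):
            a1 = A[j, i1] if i1 is not None else 0.0
            a2 = A[j, i2] if i2 is not None else 0.0
            val = 0.5 * (a1 + a2)
            A[i, j] = A[j, i] = val
    # present in the input order for stable round-trips
    order = np.array([pos[g] for g in p.parents])
    A = A[np.ix_(order, order)]
    return RelationshipMatrix(ids=list(p.parents), values=A, kind="A")


# ---------------------------------------------------------------------------
# hyperspectral H
# ---------------------------------------------------------------------------

def build_h_matrix(
    band_blues: pd.DataFrame, ddof: int = 1
) -> RelationshipMatrix:
    """H = SS'/nbands from a line x band table of adjusted means.

    Each band column is centred and scaled to unit standard deviation
    (``ddof=1``: sample sd, the default; ``ddof=0``: population sd — a global
    rescaling of H only).  Constant bands carry no contrast between lines and
    are dropped with a warning; the divisor is the retained band count.
    """
    if len(band_blues) < 2:
        raise DegenerateInputError("H requires at least two lines")
    X = band_blues.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        # every band constant: centring annihilates S -> zero matrix
        n = len(band_blues)
        return RelationshipMatrix(
            ids=[str(i) for i in band_blues.index], values=np.zeros((n, n)),
            kind="H", scope="genotype-within-site-year",
        )
    if not keep.all():
        logger.warning("dropping %d constant spectral bands", int((~keep).sum()))
    S = Xc[:, keep] / sd[keep]
    H = (S @ S.T) / keep.sum()
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(
        ids=[str(i) for i in band_blues.index], values=H,
        kind="H", scope="genotype-within-site-year",
    )


# ---------------------------------------------------------------------------
# record-level expansion
# ---------------------------------------------------------------------------

def expand_kernel(
    k: RelationshipMatrix | dict[str, RelationshipMatrix],
    idx: RecordIndex,
    mode: str,
) -> np.ndarray:
    """Lift a genotype-level kernel to the record (site-year x genotype) level.

    mode "main":    Z_g K Z_g'   — genetic main effect covariance.
    mode "gxe":     (Z_g K Z_g') ∘ (Z_E Z_E') — interaction covariance; exact
                    zeros between records from different site-years.
    mode "block_h": block-diagonal assembly of per-site-year H matrices
                    (``k`` is a mapping site_year -> RelationshipMatrix).
    """
    n = idx.n_records
    if mode in ("main", "gxe"):
        if not isinstance(k, RelationshipMatrix):
            raise TypeError("main/gxe expansion expects a single RelationshipMatrix")
        lines = idx.records["line_id"].tolist()
        C = k.submatrix(lines)
        if mode == "gxe":
            same_sy = (idx.site_year_of[:, None] == idx.site_year_of[None, :])
            C = np.where(same_sy, C, 0.0)
        return C
    if mode == "block_h":
        if not isinstance(k, dict):
            raise TypeError("block_h expansion expects {site_year: RelationshipMatrix}")
        C = np.zeros((n, n))
        for sy_i, sy in enumerate(idx.site_years):
            mask = idx.site_year_of == sy_i
            if sy not in k:
                raise CoverageError(f"no H block available for site-year {sy!r}")
            lines = idx.records.loc[mask, "line_id"].tolist()
            pos = np.where(mask)[0]
            C[np.ix_(pos, pos)] = k[sy].submatrix(lines)
        return C
    raise ValueError(f"unknown expansion mode {mode!r}")
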