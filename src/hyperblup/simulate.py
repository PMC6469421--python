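"""Synthetic multi-cycle, multi-treatment wheat trial generator.

Emulates the structure of a managed-treatment yield-trial series: full-sib
families of inbred lines from biparental crosses, alpha-lattice field layout
(blocks nested in replicates nested in trials), genotype-by-treatment
interaction, treatment-specific phenology, and multi-date hyperspectral
reflectance whose bands carry yield, interaction and heading-date signal.
Every dataset comes with its ground truth so downstream estimates can be
checked against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_TREATMENTS,
    MarkerMatrix,
    Pedigree,
    SpectralTable,
    site_year_key,
    validate_phenotypes,
    validate_spectra,
    write_markers,
    write_pedigree,
)

DEFAULT_TREATMENT_MEANS = {
    "Optimal Bed": 6.0,
    "Optimal Flat": 5.8,
    "Moderate Drought": 3.5,
    "Severe Drought": 2.0,
    "Heat": 3.2,
}
DEFAULT_DTHD_MEANS = {
    "Optimal Bed": 80.0,
    "Optimal Flat": 80.0,
    "Moderate Drought": 76.0,
    "Severe Drought": 71.0,
    "Heat": 62.0,
}
# late-sown heat treatment starts its clock months after the others
DEFAULT_SOWING = {t: "-12-01" for t in DEFAULT_TREATMENTS}
DEFAULT_SOWING["Heat"] = "-02-25"


@dataclass
class SimConfig:
    """All knobs of the generator; defaults emulate the study's trial design
    (3 replicates, 6 incomplete blocks per replicate, ~2 full-sibs per
    family, 5 managed treatments over 4 breeding cycles) at a desk-scale
    number of lines."""

    n_founders: int = 40
    n_families: int = 50
    sibs_per_family: int = 2
    n_checks: int = 2          # repeated check lines linking trials and cycles
    n_cycles: int = 4
    treatments: tuple = DEFAULT_TREATMENTS
    n_trials: int = 5
    reps: int = 3
    blocks_per_rep: int = 6
    n_markers: int = 600
    selfing_generations: int = 4
    # yield variance layers (t/ha)^2
    sigma2_g: float = 0.20
    sigma2_gxe: float = 0.08
    gxe_corr: float = 0.2
    sigma2_t: float = 0.10
    sigma2_r: float = 0.05
    sigma2_b: float = 0.05
    sigma2_e: float = 0.257    # 3 reps -> entry-mean heritability ~0.70
    treatment_means: dict = field(default_factory=lambda: dict(DEFAULT_TREATMENT_MEANS))
    # phenology (days)
    dthd_means: dict = field(default_factory=lambda: dict(DEFAULT_DTHD_MEANS))
    dthd_genetic_sd: float = 4.0
    dthd_sy_sd: float = 0.5
    dthd_plot_sd: float = 1.0
    dthd_gy_corr: float = 0.3
    dtmt_offset: float = 35.0
    dtmt_sd: float = 1.5
    # hyperspectral layer
    n_bands: int = 62
    band_min: float = 398.0
    band_max: float = 847.0
    stage_signal: dict = field(default_factory=lambda: {"VEG": 0.4, "HEAD": 0.7, "GF": 1.0})
    band_bv_scale: float = 0.04
    band_gxe_scale: float = 0.04
    band_dthd_scale: float = 0.004
    band_noise_sd: float = 0.03
    # non-genetic line-level spectral deviation, persistent across the
    # replicates and dates of a site-year: it does not average out and
    # bounds how well spectra can proxy genetic merit
    band_line_noise_sd: float = 0.03
    band_corr_length: float = 8.0
    date_offset_sd: float = 0.05
    design_reflect_sd: float = 0.01
    drop_veg_cycles: tuple = ()
    master_seed: int = 20190222

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_gxe", "sigma2_t", "sigma2_r",
                     "sigma2_b", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_founders", "n_families", "sibs_per_family", "n_cycles",
                     "n_trials", "reps", "blocks_per_rep", "n_markers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def cycle_labels(self) -> list[str]:
        return [f"{2013 + c}-{14 + c}" for c in range(self.n_cycles)]

    @property
    def lines_per_cycle(self) -> int:
        return self.n_families * self.sibs_per_family


def residual_for_h2(sigma2_g: float, h2: float, nreps: int = 3) -> float:
    """Residual variance that yields entry-mean heritability ``h2``."""
    return nreps * sigma2_g * (1.0 / h2 - 1.0)


@dataclass
class SimTruth:
    bv: pd.Series                    # breeding value per line (t/ha)
    heading_gv: pd.Series            # genetic heading deviation per line (days)
    gxe: pd.DataFrame                # line x site_year interaction deviation
    plot_design_effect: pd.Series    # trial+rep+block effect per plot
    band_gy_corr: pd.DataFrame       # (site_year, date, band) structural corr
    band_loadings: pd.DataFrame      # per-band loading on bv / gxe / heading


@dataclass
class SyntheticDataset:
    phenotypes: pd.DataFrame
    spectra: SpectralTable
    markers: MarkerMatrix
    pedigree: Pedigree
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _self_locus(codes: np.ndarray, gens: int, rng) -> np.ndarray:
    """Advance heterozygous dosages through selfing generations."""
    out = codes.astype(float).copy()
    for _ in range(gens):
        het = out == 1.0
        if not het.any():
            break
        draws = rng.choice([0.0, 1.0, 2.0], size=het.sum(), p=[0.25, 0.5, 0.25])
        out[het] = draws
    return out


def simulate_population(cfg: SimConfig, rng=None):
    """Founders, full-sib progeny markers, pedigree and true genetic values."""
    rng = rng or np.random.default_rng(cfg.master_seed)
    p = rng.uniform(0.1, 0.9, cfg.n_markers)
    founder_codes = 2.0 * (rng.random((cfg.n_founders, cfg.n_markers)) < p)
    founder_ids = [f"F{i:03d}" for i in range(cfg.n_founders)]

    parents: dict[str, tuple[str | None, str | None]] = {
        f: (None, None) for f in founder_ids
    }
    line_ids: list[str] = []
    codes_rows: list[np.ndarray] = []
    for c, cyc in enumerate(cfg.cycle_labels):
        for fam in range(cfg.n_families):
            i1, i2 = rng.choice(cfg.n_founders, size=2, replace=False)
            f1 = 0.5 * (founder_codes[i1] + founder_codes[i2])
            for sib in range(cfg.sibs_per_family):
                lid = f"C{c}_{fam:03d}_{sib}"
                line_ids.append(lid)
                codes_rows.append(_self_locus(f1, cfg.selfing_generations, rng))
                parents[lid] = (founder_ids[i1], founder_ids[i2])

    # repeated checks: extra lines sown in every replicate of every trial
    for k in range(cfg.n_checks):
        i1, i2 = rng.choice(cfg.n_founders, size=2, replace=False)
        f1 = 0.5 * (founder_codes[i1] + founder_codes[i2])
        lid = f"CHK{k}"
        line_ids.append(lid)
        codes_rows.append(_self_locus(f1, cfg.selfing_generations, rng))
        parents[lid] = (founder_ids[i1], founder_ids[i2])

    codes = np.vstack(codes_rows)
    markers = MarkerMatrix(
        line_ids=line_ids,
        marker_ids=[f"M{k:04d}" for k in range(cfg.n_markers)],
        codes=codes,
    )
    pedigree = Pedigree(parents=parents)

    alpha = rng.standard_normal(cfg.n_markers)
    bv_raw = (codes - codes.mean(axis=0)) @ alpha
    sd = bv_raw.std()
    bv = bv_raw * (np.sqrt(cfg.sigma2_g) / sd if sd > 0 else 0.0)
    bv = pd.Series(bv, index=line_ids, name="bv")

    z = rng.standard_normal(len(line_ids))
    bv_std = (bv - bv.mean()) / max(bv.std(), 1e-12)
    rho = cfg.dthd_gy_corr
    heading = cfg.dthd_genetic_sd * (rho * bv_std.to_numpy() + np.sqrt(1 - rho**2) * z)
    heading_gv = pd.Series(heading, index=line_ids, name="heading_gv")
    return markers, pedigree, bv, heading_gv


# ---------------------------------------------------------------------------
# trials + spectra
# ---------------------------------------------------------------------------

def _smooth_curve(n: int, length: float, rng) -> np.ndarray:
    """Unit-variance draw from a squared-exponential GP over band index."""
    idx = np.arange(n)
    cov = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / length) ** 2)
    L = np.linalg.cholesky(cov + 1e-8 * np.eye(n))
    return L @ rng.standard_normal(n)


def _cycle_of(line_id: str) -> int:
    return int(line_id.split("_")[0][1:])


def simulate_trials(pop, cfg: SimConfig, rng=None) -> SyntheticDataset:
    markers, pedigree, bv, heading_gv = pop
    rng = rng or np.random.default_rng(cfg.master_seed + 1)
    wavelengths = np.linspace(cfg.band_min, cfg.band_max, cfg.n_bands)
    band_cols = [f"b{int(round(w))}" for w in wavelengths]

    # band loading curves, fixed for the whole study
    baseline = 0.25 + 0.1 * _smooth_curve(cfg.n_bands, cfg.band_corr_length, rng)
    a_load = cfg.band_bv_scale * _smooth_curve(cfg.n_bands, cfg.band_corr_length, rng)
    g_load = cfg.band_gxe_scale * _smooth_curve(cfg.n_bands, cfg.band_corr_length, rng)
    c_load = cfg.band_dthd_scale * _smooth_curve(cfg.n_bands, cfg.band_corr_length, rng)
    noise_cov = np.exp(
        -0.5 * ((np.arange(cfg.n_bands)[:, None] - np.arange(cfg.n_bands)[None, :])
                / cfg.band_corr_length) ** 2
    )
    noise_L = np.linalg.cholesky(noise_cov + 1e-8 * np.eye(cfg.n_bands)) * cfg.band_noise_sd

    T = len(cfg.treatments)
    codes_df = pd.DataFrame(markers.codes, index=markers.line_ids)

    pheno_rows = []
    spectra_rows = []
    gxe_records = {}
    design_effects = {}
    corr_rows = []

    all_lines = list(bv.index)
    check_ids = [l for l in all_lines if l.startswith("CHK")]
    for c, cyc in enumerate(cfg.cycle_labels):
        cyc_lines = [
            l for l in all_lines if not l.startswith("CHK") and _cycle_of(l) == c
        ]
        sy_lines = cyc_lines + check_ids
        order = list(rng.permutation(cyc_lines))
        trial_of = {l: (i % cfg.n_trials) + 1 for i, l in enumerate(order)}
        trial_groups = {
            t: [l for l in order if trial_of[l] == t]
            for t in range(1, cfg.n_trials + 1)
        }
        # genetic interaction deviations: treatment-specific marker effects,
        # correlated across treatments, so deviations are heritable and
        # correlated across lines through realised genomic relationship
        Zc = codes_df.loc[sy_lines].to_numpy()
        Zc = Zc - Zc.mean(axis=0)
        common = rng.standard_normal(cfg.n_markers)
        gxe_cols = {}
        for treat in cfg.treatments:
            specific = rng.standard_normal(cfg.n_markers)
            delta = (np.sqrt(cfg.gxe_corr) * common
                     + np.sqrt(1.0 - cfg.gxe_corr) * specific)
            raw = Zc @ delta
            sd = raw.std()
            gxe_cols[treat] = raw * (np.sqrt(cfg.sigma2_gxe) / sd if sd > 0 else 0.0)
        gxe_df = pd.DataFrame(gxe_cols, index=sy_lines)

        for ti, treat in enumerate(cfg.treatments):
            sy = site_year_key(cyc, treat)
            gxe_records[sy] = gxe_df[treat]
            sow_year = 2013 + c + (1 if treat == "Heat" else 0)
            sowing = f"{sow_year}{DEFAULT_SOWING.get(treat, '-12-01')}"
            mean_gy = cfg.treatment_means.get(treat, 4.0)
            dthd_base = cfg.dthd_means.get(treat, 75.0)

            t_eff = rng.normal(0, np.sqrt(cfg.sigma2_t), cfg.n_trials)
            r_eff = rng.normal(0, np.sqrt(cfg.sigma2_r), (cfg.n_trials, cfg.reps))
            b_eff = rng.normal(
                0, np.sqrt(cfg.sigma2_b), (cfg.n_trials, cfg.reps, cfg.blocks_per_rep)
            )
            # line-level heading value in this site-year
            dthd_line = (
                dthd_base
                + heading_gv[sy_lines]
                + rng.normal(0, cfg.dthd_sy_sd, len(sy_lines))
            )
            dthd_line = pd.Series(dthd_line.to_numpy(), index=sy_lines)
            dtmt_line = dthd_line + cfg.dtmt_offset + rng.normal(0, cfg.dtmt_sd, len(sy_lines))
            dtmt_line = pd.Series(np.maximum(dtmt_line, dthd_line + 5.0), index=sy_lines)

            plot_records = []
            for t in range(1, cfg.n_trials + 1):
                lines_t = trial_groups[t] + check_ids
                for r in range(1, cfg.reps + 1):
                    perm = list(rng.permutation(lines_t))
                    blocks = np.array_split(perm, cfg.blocks_per_rep)
                    for bi, block_lines in enumerate(blocks, start=1):
                        for l in block_lines:
                            pid = f"{cyc}|{treat}|{t}-{r}-{l}"
                            design = t_eff[t - 1] + r_eff[t - 1, r - 1] + b_eff[t - 1, r - 1, bi - 1]
                            gy = (
                                mean_gy + bv[l] + gxe_df.at[l, treat] + design
                                + rng.normal(0, np.sqrt(cfg.sigma2_e))
                            )
                            rec = {
                                "plot_id": pid,
                                "line_id": l,
                                "cycle": cyc,
                                "treatment": treat,
                                "trial": t,
                                "replicate": r,
                                "block": bi,
                                "gy": max(gy, 0.0),
                                "lodging": 0.0,
                                "dthd": np.nan,
                                "dtmt": np.nan,
                                "is_check": l in check_ids,
                                "sowing_date": sowing,
                            }
                            if r == 1:  # phenology scored in the first replicate only
                                d = dthd_line[l] + rng.normal(0, cfg.dthd_plot_sd)
                                rec["dthd"] = round(float(d), 1)
                                rec["dtmt"] = round(float(max(dtmt_line[l], d + 3.0)), 1)
                            design_effects[pid] = design
                            plot_records.append(rec)
            pheno_rows.extend(plot_records)

            # persistent line-level spectral deviation for this site-year
            line_dev = (
                rng.standard_normal((len(sy_lines), cfg.n_bands)) @ noise_L.T
                * (cfg.band_line_noise_sd / max(cfg.band_noise_sd, 1e-12))
            )
            line_dev_df = pd.DataFrame(line_dev, index=sy_lines)

            # phenotyping dates placed around the heading distribution
            m = float(dthd_line.mean())
            date_days = [m - 15, m - 5, m + 3, m + 12, m + 25]
            sow_ts = pd.Timestamp(sowing)
            head_ts = sow_ts + pd.to_timedelta(dthd_line, unit="D")
            mat_ts = sow_ts + pd.to_timedelta(dtmt_line, unit="D")
            plot_df = pd.DataFrame(plot_records)
            for day in date_days:
                ts = sow_ts + pd.Timedelta(days=round(day))
                frac_head = float((head_ts <= ts).mean())
                if frac_head < 0.5:
                    stage = "VEG"
                elif frac_head < 1.0:
                    stage = "HEAD"
                else:
                    stage = "GF" if float((mat_ts <= ts).mean()) < 1.0 else "GF"
                if stage == "VEG" and cyc in cfg.drop_veg_cycles:
                    continue
                s = cfg.stage_signal.get(stage, 1.0)
                date_str = ts.strftime("%Y-%m-%d")
                offset = cfg.date_offset_sd * _smooth_curve(cfg.n_bands, cfg.band_corr_length, rng)

                # structural (noise-free, line-level) band signal for truth
                bv_v = bv[plot_df["line_id"]].to_numpy()
                gxe_v = gxe_df[treat][plot_df["line_id"]].to_numpy()
                hg_v = heading_gv[plot_df["line_id"]].to_numpy()
                d_t = rng.normal(0, cfg.design_reflect_sd, cfg.n_trials)
                d_r = rng.normal(0, cfg.design_reflect_sd, (cfg.n_trials, cfg.reps))
                signal = (
                    s * (np.outer(bv_v, a_load) + np.outer(gxe_v, g_load))
                    + np.outer(hg_v, c_load)
                )
                noise = rng.standard_normal((len(plot_df), cfg.n_bands)) @ noise_L.T
                refl = (
                    baseline[None, :]
                    + offset[None, :]
                    + signal
                    + line_dev_df.loc[plot_df["line_id"]].to_numpy()
                    + noise
                    + d_t[plot_df["trial"] - 1][:, None]
                    + d_r[plot_df["trial"] - 1, plot_df["replicate"] - 1][:, None]
                )
                spec_df = pd.DataFrame(refl, columns=band_cols)
                spec_df.insert(0, "date", date_str)
                spec_df.insert(0, "plot_id", plot_df["plot_id"].to_numpy())
                spectra_rows.append(spec_df)

                # truth: correlation of the structural band signal with the
                # genetic yield signal, over the lines of this site-year
                uniq = plot_df.drop_duplicates("line_id")
                bvu = bv[uniq["line_id"]].to_numpy()
                gxu = gxe_df[treat][uniq["line_id"]].to_numpy()
                hgu = heading_gv[uniq["line_id"]].to_numpy()
                gy_sig = bvu + gxu
                sig_u = (
                    s * (np.outer(bvu, a_load) + np.outer(gxu, g_load))
                    + np.outer(hgu, c_load)
                    + line_dev_df.loc[uniq["line_id"]].to_numpy()
                )
                gy_c = gy_sig - gy_sig.mean()
                sig_c = sig_u - sig_u.mean(axis=0)
                denom = np.sqrt((sig_c**2).sum(axis=0) * (gy_c**2).sum())
                with np.errstate(invalid="ignore", divide="ignore"):
                    r_struct = np.where(denom > 0, sig_c.T @ gy_c / denom, 0.0)
                for b_i, bc in enumerate(band_cols):
                    corr_rows.append(
                        {"site_year": sy, "date": date_str, "stage": stage,
                         "band": bc, "corr": r_struct[b_i]}
                    )

    phenotypes = validate_phenotypes(
        pd.DataFrame(pheno_rows), treatments=tuple(cfg.treatments)
    )
    spectra = validate_spectra(
        pd.concat(spectra_rows, ignore_index=True), expected_nbands=cfg.n_bands
    )
    truth = SimTruth(
        bv=bv,
        heading_gv=heading_gv,
        gxe=pd.DataFrame(gxe_records),
        plot_design_effect=pd.Series(design_effects, name="design_effect"),
        band_gy_corr=pd.DataFrame(corr_rows),
        band_loadings=pd.DataFrame(
            {"bv": a_load, "gxe": g_load, "dthd": c_load}, index=band_cols
        ),
    )
    return SyntheticDataset(
        phenotypes=phenotypes, spectra=spectra, markers=markers,
        pedigree=pedigree, truth=truth, config=cfg,
    )


def simulate_dataset(cfg: SimConfig, seed: int | None = None) -> SyntheticDataset:
    """One-shot generation: population + trials + spectra, fully seeded."""
    seed = cfg.master_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    pop = simulate_population(cfg, rng)
    return simulate_trials(pop, cfg, rng)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def make_scenario(name: str) -> SimConfig:
    """Named study conditions used throughout the test battery.

    baseline              4 cycles x 5 treatments, moderate G x E
    strong_gxe            2 cycles x 3 treatments x 300 lines; interaction
                          variance and spectral interaction loading inflated
    phenology_confounded  spectra load heavily on heading date, which is
                          itself strongly correlated with yield
    missing_stage         baseline but one cycle lacks all VEG dates
    """
    base = SimConfig()
    if name == "baseline":
        return base
    if name == "strong_gxe":
        return replace(
            base,
            n_cycles=2,
            treatments=("Optimal Bed", "Moderate Drought", "Heat"),
            n_families=75,
            n_founders=25,
            sigma2_gxe=0.30,
            gxe_corr=0.15,
            band_gxe_scale=0.06,
            band_bv_scale=0.03,
            band_line_noise_sd=0.05,
        )
    if name == "phenology_confounded":
        return replace(
            base,
            n_cycles=2,
            treatments=("Optimal Bed", "Moderate Drought", "Heat"),
            n_families=75,
            n_founders=25,
            dthd_gy_corr=0.35,
            band_dthd_scale=0.045,
            band_bv_scale=0.015,
            band_gxe_scale=0.03,
            band_line_noise_sd=0.04,
        )
    if name == "missing_stage":
        cfg = replace(base, n_cycles=2, treatments=("Optimal Bed", "Moderate Drought"))
        return replace(cfg, drop_veg_cycles=(cfg.cycle_labels[0],))
    raise ValueError(f"unknown scenario {name!r}")


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Emit the four standard CSVs plus the truth bundle."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.phenotypes.drop(columns=["site_year"]).to_csv(out / "phenotypes.csv", index=False)
    ds.spectra.frame.to_csv(out / "spectra.csv", index=False)
    write_markers(ds.markers, out / "markers.csv")
    write_pedigree(ds.pedigree, out / "pedigree.csv")
    ds.truth.bv.to_csv(out / "truth_breeding_values.csv", index_label="line_id")
    ds.truth.heading_gv.to_csv(out / "truth_heading.csv", index_label="line_id")
    ds.truth.gxe.to_csv(out / "truth_gxe.csv", index_label="line_id")
    ds.truth.band_gy_corr.to_csv(out / "truth_band_gy_corr.csv", index=False)
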