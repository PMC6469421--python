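import numpy as np
import pandas as pd
import pytest

from hyperblup.io import CoverageError, SpectralTable
from hyperblup.reml import MixedModelEngine, solve_mme_dense
from hyperblup.stagewise import (
    EmptyScopeError,
    PlotMixedModel,
    classify_time_points,
    fit_band_blues,
    fit_trait_blues,
    heritability,
    reml_fit,
)
from hyperblup.pipeline import site_year_tables


def one_way_frame(means, reps=4, noise=None, rng=None):
    rows = []
    for i, mu in enumerate(means):
        for r in range(reps):
            y = mu if noise is None else mu + rng.normal(0, noise)
            rows.append({"plot_id": f"p{i}_{r}", "line_id": f"L{i}",
                         "trial": 1, "replicate": r + 1, "block": 1, "y": y})
    return pd.DataFrame(rows)


class TestRemlEngine:
    def test_balanced_one_way_blues_are_means(self, rng):
        df = one_way_frame([4.0, 5.0, 6.0], noise=0.3, rng=rng)
        fit = reml_fit(df, "y", random_terms=[], genotype_role="fixed")
        means = df.groupby("line_id")["y"].mean()
        np.testing.assert_allclose(fit.blues[means.index], means.to_numpy(), atol=1e-10)

    def test_fixed_variance_blup_equals_dense_mme(self, rng):
        # n <= 50: engine solution path vs explicit Henderson equations
        n, q = 40, 8
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = np.zeros((n, q))
        Z[np.arange(n), rng.integers(0, q, n)] = 1.0
        y = rng.normal(size=n)
        s2u, s2e = 0.6, 0.4
        res = solve_mme_dense(y, X, [("u", Z)], {"u": s2u, "residual": s2e})
        lam = s2e / s2u
        LHS = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(q)]])
        sol = np.linalg.solve(LHS, np.concatenate([X.T @ y, Z.T @ y]))
        np.testing.assert_allclose(np.concatenate([res.beta, res.u["u"]]), sol, atol=1e-8)

    def test_restricted_likelihood_not_below_truth(self, rng):
        """The optimiser's solution is at least as likely as the generating values."""
        n = 200
        Z = np.zeros((n, 20))
        Z[np.arange(n), rng.integers(0, 20, n)] = 1.0
        truth = {"u": 0.5, "residual": 1.0}
        y = Z @ rng.normal(0, np.sqrt(truth["u"]), 20) + rng.normal(0, 1, n)
        eng = MixedModelEngine(np.ones((n, 1)), [("u", Z)])
        fit = eng.fit(y)
        ll_at_truth = eng.solve_blup(y, truth).loglik
        assert fit.loglik >= ll_at_truth - 1e-6

    def test_blue_shift_invariance(self, rng):
        df = one_way_frame([4.0, 5.0], reps=3, noise=0.2, rng=rng)
        base = reml_fit(df, "y", random_terms=[], genotype_role="fixed").blues
        df2 = df.assign(y=df["y"] + 7.0)
        shifted = reml_fit(df2, "y", random_terms=[], genotype_role="fixed").blues
        np.testing.assert_allclose(shifted - base, 7.0, atol=1e-8)


class TestTraitBlues:
    def test_blup_shrinkage(self, tiny_dataset):
        sy, plots = next(site_year_tables(tiny_dataset.phenotypes))
        blue = fit_trait_blues(plots, "gy", genotype_role="fixed")
        blup = fit_trait_blues(plots, "gy", genotype_role="random")
        assert blup.blups.var() < blue.blues.var()

    def test_single_replicate_drops_rep_block(self, tiny_dataset):
        sy, plots = next(site_year_tables(tiny_dataset.phenotypes))
        fit = fit_trait_blues(plots, "dthd")  # scored in replicate 1 only
        assert fit.model_terms["random"] == ["trial"]

    def test_lodging_covariate_dropped_when_unobserved(self, tiny_dataset):
        sy, plots = next(site_year_tables(tiny_dataset.phenotypes))
        assert (plots["lodging"].fillna(0) == 0).all()
        fit = fit_trait_blues(plots, "gy", covariates=("lodging",))
        assert fit.model_terms["covariates"] == []

    def test_heritability_arithmetic(self):
        assert heritability(1.0, 0.0) == pytest.approx(1.0)
        assert heritability(1.0, 3.0, nreps=3) == pytest.approx(0.5)
        assert heritability(1.0, 3.0) == pytest.approx(0.5)  # nreps defaults to 3
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)


class TestStageClassification:
    def _plots(self, dthd, dtmt=None):
        n = len(dthd)
        return pd.DataFrame({
            "plot_id": [f"p{i}" for i in range(n)],
            "line_id": [f"L{i}" for i in range(n)],
            "dthd": dthd,
            "dtmt": dtmt if dtmt is not None else [d + 35 for d in dthd],
            "sowing_date": "2013-12-01",
        })

    def test_threshold_rules(self):
        # 10 lines head on days 70..79; maturity 35 d later
        plots = self._plots(list(range(70, 80)))
        labels = classify_time_points(
            plots, ["2014-02-10", "2014-02-14", "2014-02-18", "2014-03-20"]
        )
        # day offsets from sowing: 71, 75, 79, 109
        assert labels["stage"].tolist() == ["VEG", "HEAD", "GF", "GF"]

    def test_thirty_percent_headed_is_veg(self):
        plots = self._plots([60] * 3 + [90] * 7)  # 30% headed at day 70
        lab = classify_time_points(plots, ["2014-02-09"])
        assert lab.loc[0, "stage"] == "VEG"

    def test_all_headed_partially_mature_is_gf(self):
        plots = self._plots([60] * 10, dtmt=[80] * 4 + [120] * 6)
        lab = classify_time_points(plots, ["2014-03-15"])  # day 104: 40% mature
        assert lab.loc[0, "stage"] == "GF"

    def test_after_full_maturity_strict_errors(self):
        plots = self._plots([60] * 4, dtmt=[80] * 4)
        with pytest.raises(ValueError, match="maturity"):
            classify_time_points(plots, ["2014-06-01"], strict=True)
        lab = classify_time_points(plots, ["2014-06-01"], strict=False)
        assert lab.loc[0, "stage"] == "GF"

    def test_monotone_stages_on_generated_data(self, tiny_dataset):
        order = {"VEG": 0, "HEAD": 1, "GF": 2}
        for sy, plots in site_year_tables(tiny_dataset.phenotypes):
            sy_plots = set(plots["plot_id"])
            dates = sorted(
                tiny_dataset.spectra.frame.loc[
                    tiny_dataset.spectra.frame["plot_id"].isin(sy_plots), "date"
                ].unique()
            )
            lab = classify_time_points(plots, dates)
            codes = [order[s] for s in lab["stage"]]
            assert codes == sorted(codes)

    def test_insufficient_phenology_coverage(self):
        plots = self._plots([60.0] * 10)
        plots.loc[:5, "dthd"] = np.nan
        with pytest.raises(CoverageError):
            classify_time_points(plots, ["2014-02-01"])


class TestBandBlues:
    def _spectra_for(self, plots, dates, fn):
        rows = []
        for d in dates:
            for _, p in plots.iterrows():
                rows.append({"plot_id": p["plot_id"], "date": d,
                             "b500": fn(p, d), "b600": fn(p, d) + 0.1})
        return SpectralTable(frame=pd.DataFrame(rows), band_columns=["b500", "b600"])

    def _plots(self, n=6, reps=2):
        rows = []
        for i in range(n):
            for r in range(reps):
                rows.append({"plot_id": f"p{i}_{r}", "line_id": f"L{i}",
                             "trial": 1, "replicate": r + 1, "block": 1 + (i + r) % 2,
                             "dthd": 70.0 + i, "dtmt": 110.0 + i,
                             "sowing_date": "2013-12-01"})
        return pd.DataFrame(rows)

    def test_single_date_no_design_variance_gives_plot_means(self):
        plots = self._plots()
        vals = {f"L{i}": 0.3 + 0.02 * i for i in range(6)}
        spectra = self._spectra_for(plots, ["2014-02-20"],
                                    lambda p, d: vals[p["line_id"]])
        bbt = fit_band_blues(plots, spectra, "2014-02-20")
        got = bbt.blues["b500"]
        np.testing.assert_allclose(
            got[sorted(vals)], [vals[k] for k in sorted(vals)], atol=1e-8
        )

    def test_pure_date_offset_absorbed(self, rng):
        # two dates differing by an additive offset: stage BLUEs keep ranking
        plots = self._plots()
        vals = {f"L{i}": 0.3 + 0.02 * i for i in range(6)}
        offset = {"2014-02-20": 0.0, "2014-02-25": 0.3}
        spectra = self._spectra_for(plots, list(offset),
                                    lambda p, d: vals[p["line_id"]] + offset[d])
        bbt = fit_band_blues(plots, spectra, "ALL")
        got = bbt.blues["b500"].sort_index()
        diffs = np.diff(got.to_numpy())
        np.testing.assert_allclose(diffs, 0.02, atol=1e-6)

    def test_missing_stage_raises_empty_scope(self):
        plots = self._plots()
        # both dates fall after every line has headed -> no VEG dates
        spectra = self._spectra_for(plots, ["2014-03-01", "2014-03-05"],
                                    lambda p, d: 0.4)
        with pytest.raises(EmptyScopeError, match="VEG"):
            fit_band_blues(plots, spectra, "VEG")


def test_band_heritability_recovery():
    """Per-band H2 estimated by the pipeline matches the generator's implied
    band heritability (pure breeding-value loadings, known noise) within 0.1."""
    from dataclasses import replace
    from hyperblup.simulate import SimConfig, simulate_dataset
    from hyperblup.stagewise import heritability as h2

    cfg = replace(
        SimConfig(),
        n_cycles=1, treatments=("Optimal Bed",), n_families=100, n_founders=20,
        n_trials=4, n_markers=200, n_bands=8,
        band_bv_scale=0.08, band_gxe_scale=0.0, band_dthd_scale=0.0,
        band_line_noise_sd=0.0, design_reflect_sd=0.0, band_noise_sd=0.04,
    )
    ds = simulate_dataset(cfg, seed=17)
    plots = ds.phenotypes
    frame = ds.spectra.frame
    # last date: grain fill, stage signal multiplier 1.0
    date = sorted(frame["date"].unique())[-1]
    stage = ds.truth.band_gy_corr.query("date == @date")["stage"].iloc[0]
    s = cfg.stage_signal[stage]
    sub = frame.loc[frame["date"] == date].merge(
        plots[["plot_id", "line_id", "trial", "replicate", "block"]], on="plot_id"
    )
    errs = []
    for band in ds.spectra.band_columns:
        a = ds.truth.band_loadings.loc[band, "bv"]
        sig_g = (s * a) ** 2 * cfg.sigma2_g
        expected = sig_g / (sig_g + cfg.band_noise_sd**2 / 3)
        fit = reml_fit(sub, band, random_terms=["trial", ("trial", "replicate"),
                                                ("trial", "replicate", "block")],
                       genotype_role="random")
        got = h2(fit.varcomp.sigma2_g, fit.varcomp.sigma2_e, nreps=3)
        errs.append(abs(got - expected))
    assert np.mean(errs) < 0.1
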