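import numpy as np
import pandas as pd
import pytest

from hyperblup.io import CoverageError, build_record_index, validate_phenotypes
from hyperblup.kernels import RelationshipMatrix
from hyperblup.gblup import (
    GblupSpec,
    GibbsSettings,
    KernelTerm,
    MultiKernelGBLUP,
    assemble_model,
    fit_gblup,
    predict_masked,
)
from .conftest import toy_phenotypes


def grid_index(n_lines, site_years):
    phen = validate_phenotypes(toy_phenotypes(n_lines=n_lines, site_years=site_years))
    phen["plot_id"] = [f"p{i}" for i in range(len(phen))]
    return build_record_index(phen)


def random_psd(rng, ids):
    Z = rng.normal(size=(len(ids), len(ids) + 3))
    return RelationshipMatrix(ids=list(ids), values=Z @ Z.T / len(ids), kind="G")


def single_kernel_spec(idx, K, y, name="G"):
    from hyperblup.kernels import expand_kernel

    X = np.ones((idx.n_records, 1))
    if len(idx.site_years) > 1:
        X = np.column_stack(
            [np.ones(idx.n_records)]
            + [(idx.site_year_of == j).astype(float) for j in range(1, len(idx.site_years))]
        )
    cov = expand_kernel(K, idx, "main")
    return GblupSpec(idx=idx, y=y, X=X, terms=[KernelTerm(name, "G", "main", cov)],
                     model_name=name)


class TestAssembleModel:
    def _kernels(self, rng, idx):
        from hyperblup.kernels import build_h_matrix

        hs = {
            sy: build_h_matrix(pd.DataFrame(rng.normal(size=(len(idx.genotypes), 5)),
                                            index=idx.genotypes))
            for sy in idx.site_years
        }
        return {"G": random_psd(rng, idx.genotypes),
                "A": random_psd(rng, idx.genotypes),
                "H": {"VEG": {}, "ALL": hs}}

    def test_single_kernel_g(self, rng):
        idx = grid_index(5, (("2013-14", "Heat"),))
        spec = assemble_model("G", self._kernels(rng, idx), idx)
        assert len(spec.terms) == 1
        assert (spec.terms[0].source, spec.terms[0].mode) == ("G", "main")
        assert spec.X.shape[1] == 1  # no site-year term for a single site-year

    def test_multi_kernel_a_plus_a_gxe(self, rng):
        idx = grid_index(5, (("2013-14", "Heat"), ("2014-15", "Heat")))
        spec = assemble_model("A+A_GxE", self._kernels(rng, idx), idx)
        assert [(t.source, t.mode) for t in spec.terms] == [("A", "main"), ("A", "gxe")]
        assert spec.X.shape[1] == 2

    def test_h_block_and_missing_stage_coverage(self, rng):
        idx = grid_index(5, (("2013-14", "Heat"), ("2014-15", "Heat")))
        k = self._kernels(rng, idx)
        spec = assemble_model("G+H.ALL_GxE", k, idx)
        assert [(t.source, t.mode) for t in spec.terms] == [("G", "main"), ("H", "block_h")]
        with pytest.raises(CoverageError):
            assemble_model("G+H.VEG_GxE", k, idx)


class TestFitGblup:
    def test_fixed_variance_matches_dense_henderson(self, rng):
        """Single kernel, fixed variances, n <= 50: ridge/MME closed form."""
        idx = grid_index(40, (("2013-14", "Heat"),))
        n = idx.n_records
        K = random_psd(rng, idx.genotypes)
        K.values += 0.1 * np.eye(n)  # full rank so K^-1 exists for the oracle
        y = rng.normal(4.0, 1.0, n)
        y[rng.choice(n, 10, replace=False)] = np.nan
        spec = single_kernel_spec(idx, K, y)
        fv = {"G": 0.8, "residual": 0.4}
        fit = fit_gblup(spec, method="em_reml", fixed_variances=fv)
        # independent dense Henderson solve with Z = I on training rows
        obs = ~np.isnan(y)
        from hyperblup.kernels import expand_kernel
        C = expand_kernel(K, idx, "main")
        Xo = spec.X[obs]
        Zo = np.eye(n)[obs]
        Cinv = np.linalg.inv(C)
        LHS = np.block([
            [Xo.T @ Xo, Xo.T @ Zo],
            [Zo.T @ Xo, Zo.T @ Zo + (fv["residual"] / fv["G"]) * Cinv],
        ])
        rhs = np.concatenate([Xo.T @ y[obs], Zo.T @ y[obs]])
        sol = np.linalg.solve(LHS, rhs)
        yhat = spec.X @ sol[: spec.X.shape[1]] + sol[spec.X.shape[1]:]
        np.testing.assert_allclose(fit.yhat, yhat, atol=1e-8)

    def test_masked_identity_kernel_predicts_fixed_part(self, rng):
        idx = grid_index(10, (("2013-14", "Heat"),))
        K = RelationshipMatrix(ids=idx.genotypes, values=np.eye(10), kind="G")
        y = rng.normal(0, 1, 10)
        y[3] = np.nan
        spec = single_kernel_spec(idx, K, y)
        fit = fit_gblup(spec, method="em_reml",
                        fixed_variances={"G": 1.0, "residual": 1.0})
        # with an identity kernel and no phenotype, the record's BLUP is zero,
        # so the prediction is the fixed part (the GLS intercept) alone
        obs = ~np.isnan(y)
        Xo = spec.X[obs]
        Vinv = np.linalg.inv(2.0 * np.eye(int(obs.sum())))
        b = np.linalg.solve(Xo.T @ Vinv @ Xo, Xo.T @ Vinv @ y[obs])
        assert fit.yhat[3] == pytest.approx(float(b[0]), abs=1e-8)

    def test_deterministic_given_seed(self, rng):
        idx = grid_index(12, (("2013-14", "Heat"),))
        K = random_psd(rng, idx.genotypes)
        y = rng.normal(0, 1, 12)
        y[::4] = np.nan
        spec = single_kernel_spec(idx, K, y)
        st = GibbsSettings(iterations=500, burn_in=100, thin=2, seed=5)
        f1 = fit_gblup(spec, settings=st)
        f2 = fit_gblup(spec, settings=st)
        np.testing.assert_array_equal(f1.yhat, f2.yhat)

    def test_predict_masked_covers_all_records(self, rng):
        idx = grid_index(6, (("2013-14", "Heat"),))
        K = random_psd(rng, idx.genotypes)
        y = np.full(6, np.nan)
        y[:2] = [1.0, 2.0]
        spec = single_kernel_spec(idx, K, y)
        fit = fit_gblup(spec, method="em_reml",
                        fixed_variances={"G": 1.0, "residual": 1.0})
        tab = predict_masked(fit, idx)
        assert len(tab) == 6 and tab["yhat"].notna().all()

    def test_kernel_order_exchangeable(self, rng):
        idx = grid_index(15, (("2013-14", "Heat"), ("2014-15", "Heat")))
        from hyperblup.kernels import expand_kernel
        K = random_psd(rng, idx.genotypes)
        Cm = expand_kernel(K, idx, "main")
        Cg = expand_kernel(K, idx, "gxe")
        y = rng.normal(0, 1, idx.n_records)
        y[::3] = np.nan
        X = np.column_stack([np.ones(idx.n_records),
                             (idx.site_year_of == 1).astype(float)])
        t1 = [KernelTerm("a", "G", "main", Cm), KernelTerm("b", "G", "gxe", Cg)]
        t2 = [KernelTerm("b", "G", "gxe", Cg), KernelTerm("a", "G", "main", Cm)]
        f1 = fit_gblup(GblupSpec(idx=idx, y=y, X=X, terms=t1), method="em_reml")
        f2 = fit_gblup(GblupSpec(idx=idx, y=y, X=X, terms=t2), method="em_reml")
        np.testing.assert_allclose(f1.yhat, f2.yhat, atol=1e-6)

    def test_zero_kernel_term_is_inert(self, rng):
        idx = grid_index(20, (("2013-14", "Heat"),))
        K = random_psd(rng, idx.genotypes)
        y = rng.normal(0, 1, 20)
        y[:5] = np.nan
        base = single_kernel_spec(idx, K, y)
        zero = KernelTerm("null", "G", "main", np.zeros((20, 20)))
        both = GblupSpec(idx=idx, y=y, X=base.X, terms=base.terms + [zero])
        st = GibbsSettings(iterations=2000, burn_in=500, thin=2, seed=3)
        f_base = fit_gblup(base, settings=st)
        f_both = fit_gblup(both, settings=st)
        np.testing.assert_allclose(f_base.yhat, f_both.yhat, atol=0.15)

    def test_single_site_year_gxe_duplicates_main(self, rng):
        """Model (6) degenerates with one site-year: predictions match the
        single-kernel fit within Monte-Carlo error."""
        idx = grid_index(25, (("2013-14", "Heat"),))
        from hyperblup.kernels import expand_kernel
        K = random_psd(rng, idx.genotypes)
        Cm = expand_kernel(K, idx, "main")
        Cg = expand_kernel(K, idx, "gxe")
        np.testing.assert_allclose(Cm, Cg)
        y = rng.normal(0, 1, 25)
        y[:8] = np.nan
        X = np.ones((25, 1))
        st = GibbsSettings(iterations=3000, burn_in=1000, thin=2, seed=11)
        f1 = fit_gblup(GblupSpec(idx=idx, y=y, X=X,
                                 terms=[KernelTerm("g", "G", "main", Cm)]), settings=st)
        f2 = fit_gblup(GblupSpec(idx=idx, y=y, X=X,
                                 terms=[KernelTerm("g", "G", "main", Cm),
                                        KernelTerm("ge", "G", "gxe", Cg)]), settings=st)
        r = np.corrcoef(f1.yhat, f2.yhat)[0, 1]
        assert r > 0.98

    def test_non_psd_kernel_rejected(self):
        idx = grid_index(4, (("2013-14", "Heat"),))
        bad = np.eye(4)
        bad[0, 0] = -1.0
        bad_term = KernelTerm("bad", "G", "main", bad)
        y = np.array([1.0, 2.0, np.nan, 0.5])
        spec = GblupSpec(idx=idx, y=y, X=np.ones((4, 1)), terms=[bad_term])
        with pytest.raises(ValueError, match="PSD"):
            fit_gblup(spec, method="em_reml")

    def test_shrinking_variance_ratio_converges_to_submodel(self, rng):
        """Continuity: as a term's variance ratio -> 0 its contribution vanishes."""
        idx = grid_index(15, (("2013-14", "Heat"),))
        from hyperblup.kernels import expand_kernel
        K = random_psd(rng, idx.genotypes)
        C = expand_kernel(K, idx, "main")
        y = rng.normal(0, 1, 15)
        y[:4] = np.nan
        X = np.ones((15, 1))
        terms2 = [KernelTerm("g", "G", "main", C), KernelTerm("x", "G", "main", C.copy())]
        fit_small = fit_gblup(
            GblupSpec(idx=idx, y=y, X=X, terms=terms2), method="em_reml",
            fixed_variances={"g": 0.8, "x": 1e-10, "residual": 0.4},
        )
        fit_one = fit_gblup(
            GblupSpec(idx=idx, y=y, X=X, terms=[KernelTerm("g", "G", "main", C)]),
            method="em_reml", fixed_variances={"g": 0.8, "residual": 0.4},
        )
        np.testing.assert_allclose(fit_small.yhat, fit_one.yhat, atol=1e-4)


def test_gibbs_and_reml_predictions_agree(rng):
    """Posterior-mean and REML point predictions coincide on simulated data."""
    n = 120
    ids = [f"L{i:03d}" for i in range(n)]
    phen = pd.DataFrame({"site_year": ["2013-14/Heat"] * n, "line_id": ids})
    idx = build_record_index(phen)
    K = random_psd(rng, ids)
    L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
    y = 3.0 + L @ rng.normal(0, 0.7, n) + rng.normal(0, 0.5, n)
    y[rng.choice(n, 30, replace=False)] = np.nan
    spec = single_kernel_spec(idx, K, y)
    g = fit_gblup(spec, settings=GibbsSettings(iterations=3000, burn_in=800, thin=2, seed=1))
    r = fit_gblup(spec, method="em_reml")
    assert np.corrcoef(g.yhat, r.yhat)[0, 1] > 0.99
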