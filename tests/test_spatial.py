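"""Tensor-product spatial fitting and SVG testing."""

import numpy as np
import pytest
from scipy import stats

from pretsa import (
    ExpressionMatrix,
    bic_spatial,
    fit_spatial,
    make_null,
    select_K_spatial,
    spatial_design,
    svg_test,
)

from .conftest import lstsq_oracle


def _expr(Y):
    m, n = Y.shape
    return ExpressionMatrix(
        Y, [f"g{i}" for i in range(m)], [f"c{j}" for j in range(n)]
    )


class TestFitSpatial:
    def test_plane_fitted_exactly(self):
        rng = np.random.default_rng(0)
        S = rng.uniform(size=(200, 2))
        y = 1.0 + 2.0 * S[:, 0] - 0.5 * S[:, 1]
        fit = fit_spatial(_expr(y[None, :]), S, K=0)
        np.testing.assert_allclose(fit.Yhat[0], y, atol=1e-10)

    def test_constant_gene_reproduced(self):
        rng = np.random.default_rng(1)
        S = rng.uniform(size=(100, 2))
        y = np.full(100, 4.2)
        fit = fit_spatial(_expr(y[None, :]), S, K=0)
        np.testing.assert_allclose(fit.Yhat[0], y, atol=1e-10)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-18)

    def test_matches_per_gene_lstsq_oracle_on_grid(self):
        rng = np.random.default_rng(2)
        g = np.arange(20, dtype=float)
        xs, ys = np.meshgrid(g, g, indexing="ij")
        S = np.column_stack([xs.ravel(), ys.ravel()])
        Y = rng.normal(size=(30, 400))
        design = spatial_design(S, 1)
        fit = fit_spatial(_expr(Y), S, K=1)
        ref = lstsq_oracle(design.X, Y)
        np.testing.assert_allclose(fit.Yhat, ref, rtol=1e-8, atol=1e-10)

    def test_axis_scale_invariance(self):
        # knots are built from the observed per-axis range, so rescaling
        # one coordinate axis leaves the fit unchanged
        rng = np.random.default_rng(3)
        S = rng.uniform(size=(150, 2))
        Y = rng.normal(size=(10, 150))
        f1 = fit_spatial(_expr(Y), S, K=1)
        S2 = S.copy()
        S2[:, 0] *= 37.5
        f2 = fit_spatial(_expr(Y), S2, K=1)
        np.testing.assert_allclose(f1.Yhat, f2.Yhat, atol=1e-10)

    def test_infeasible_K_errors(self):
        rng = np.random.default_rng(4)
        S = rng.uniform(size=(20, 2))
        with pytest.raises(ValueError, match="no feasible"):
            select_K_spatial(_expr(rng.normal(size=(2, 20))), S,
                             candidates=[2, 3])


class TestSelectKSpatial:
    def test_bic_penalty_uses_squared_parameter_count(self):
        y = np.zeros(100)
        yhat = np.ones(100)  # unit residual mean square
        b0 = bic_spatial(y, yhat, 0, 100)
        b1 = bic_spatial(y, yhat, 1, 100)
        assert b1 - b0 == pytest.approx((26 - 17) * np.log(100))

    def test_noise_prefers_K0(self):
        rng = np.random.default_rng(5)
        S = rng.uniform(size=(400, 2))
        expr = _expr(rng.normal(size=(30, 400)))
        sel = select_K_spatial(expr, S)
        assert sel.candidates == (0, 1, 2, 3, 4, 5)
        assert np.mean(sel.selected_K == 0) > 0.8

    def test_infeasible_candidates_skipped_for_small_n(self):
        # n = 30 admits only K=0 (p=16) and K=1 (p=25)
        rng = np.random.default_rng(6)
        S = rng.uniform(size=(30, 2))
        expr = _expr(rng.normal(size=(5, 30)))
        with pytest.warns(UserWarning):
            sel = select_K_spatial(expr, S)
        assert sel.candidates == (0, 1)


class TestSVGTest:
    def test_df_formula_for_K0(self, null_spatial):
        table = null_spatial["table"]
        assert (table["df1"] == 15).all()
        assert (table["df2"] == 900 - 16).all()

    def test_null_rejection_rate_near_nominal(self, null_spatial):
        p = null_spatial["table"]["pvalue"]
        assert 0.040 <= np.mean(p <= 0.05) <= 0.060

    def test_null_F_matches_reference_distribution(self, null_spatial):
        ks = stats.kstest(null_spatial["table"]["F"], stats.f(15, 884).cdf)
        assert ks.pvalue > 0.01

    def test_basis_member_gene_is_certain_discovery(self):
        rng = np.random.default_rng(6)
        S = rng.uniform(size=(200, 2))
        design = spatial_design(S, 0)
        # pure interaction basis function b11(s1) * b21(s2), no noise
        y = design.X[:, 1 + 3 + 3]
        expr = _expr(np.vstack([y, rng.normal(size=200)]))
        table = svg_test(fit_spatial(expr, S, K=0), expr)
        assert table.set_index("gene_id").loc["g0", "pvalue"] == 0.0

    def test_permuted_coordinates_control_false_positives(self, power_spatial):
        expr = power_spatial["expr"]
        axis = make_null(power_spatial["axis"], seed=7)
        table = svg_test(fit_spatial(expr, axis.values, K=0), expr)
        assert np.mean(table["fdr"] <= 0.05) <= 0.01


class TestRotation:
    def test_rotation_consistency_structure(self, power_spatial):
        """45-degree rotation keeps signal-gene rankings nearly intact.

        The tensor basis is axis-aligned, so pure-noise genes see two
        different projection spaces whose F statistics correlate only at
        the trace overlap of the projectors (~0.8); genes with genuine
        spatial structure stay almost perfectly concordant.
        """
        expr = power_spatial["expr"]
        truth = power_spatial["truth"]
        S = power_spatial["axis"].values
        th = np.pi / 4
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t1 = power_spatial["table"].set_index("gene_id").loc[expr.gene_ids]
        t2 = (
            svg_test(fit_spatial(expr, S @ R.T, K=0), expr)
            .set_index("gene_id")
            .loc[expr.gene_ids]
        )
        rho_all = stats.spearmanr(t1["pvalue"], t2["pvalue"]).statistic
        rho_sig = stats.spearmanr(
            t1["F"][truth], t2["F"][truth]
        ).statistic
        assert rho_all >= 0.75
        assert rho_sig >= 0.95
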