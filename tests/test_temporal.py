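"""Temporal fitting, BIC knot selection, F-test and permutation test."""

import numpy as np
import pytest
from scipy import stats

from pretsa import (
    ExpressionMatrix,
    bh_adjust,
    bic_temporal,
    f_statistic,
    fit_temporal,
    ftest_pvalues,
    make_null,
    permutation_test,
    select_K,
)
from pretsa.temporal import VAR_FLOOR, bic_from_fit

from .conftest import pvals_in_gene_order


def _expr(Y):
    m, n = Y.shape
    return ExpressionMatrix(
        Y, [f"g{i}" for i in range(m)], [f"c{j}" for j in range(n)]
    )


class TestBIC:
    def test_printed_formula_at_unit_residual(self):
        # n=10, mean squared residual exactly 1, K=0
        y = np.zeros(10)
        yhat = np.ones(10)  # residuals all 1
        expected = 5 * np.log(10) + 10 + 10 * np.log(2 * np.pi)
        assert bic_temporal(y, yhat, K=0, n=10) == pytest.approx(expected)

    def test_perfect_fit_prefers_smaller_K(self):
        y = np.linspace(0, 1, 20)
        assert bic_temporal(y, y, 0, 20) < bic_temporal(y, y, 1, 20)

    def test_doubling_residual_adds_n_log2(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        yhat = np.zeros(50)
        b1 = bic_temporal(y, yhat, 0, 50)
        b2 = bic_temporal(np.sqrt(2) * y, yhat * np.sqrt(2), 0, 50)
        assert b2 - b1 == pytest.approx(50 * np.log(2))

    def test_residual_floor_keeps_bic_finite(self):
        y = np.full(30, 1.5)
        assert np.isfinite(bic_temporal(y, y, 0, 30))
        assert bic_temporal(y, y, 0, 30) == pytest.approx(
            bic_from_fit(VAR_FLOOR, 4, 30)
        )


class TestSelectK:
    def test_single_candidate_fixes_K(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(size=100)
        expr = _expr(rng.normal(size=(20, 100)))
        sel = select_K(expr, t, candidates=[0])
        assert np.all(sel.selected_K == 0)

    def test_noise_genes_prefer_K0(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(size=500)
        expr = _expr(rng.normal(size=(100, 500)))
        sel = select_K(expr, t)
        assert np.mean(sel.selected_K == 0) > 0.8

    def test_three_hump_oscillation_selects_positive_K(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(size=300))
        y = np.sin(3 * np.pi * t) + rng.normal(0, 0.05, 300)
        sel = select_K(_expr(y[None, :]), t)
        assert sel.selected_K[0] > 0

    def test_matches_brute_force_bic_over_grid(self):
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(size=150))
        Y = np.vstack(
            [
                rng.normal(size=150),
                np.sin(2 * np.pi * t) + rng.normal(0, 0.1, 150),
                np.sin(3 * np.pi * t) + rng.normal(0, 0.05, 150),
            ]
        )
        expr = _expr(Y)
        cands = list(range(0, 11))
        sel = select_K(expr, t, candidates=cands)
        from pretsa import temporal_design

        for i in range(3):
            brute = []
            for K in cands:
                X = temporal_design(t, K).X
                beta, *_ = np.linalg.lstsq(X, Y[i], rcond=None)
                brute.append(bic_temporal(Y[i], X @ beta, K, 150))
            assert sel.selected_K[i] == cands[int(np.argmin(brute))]
            np.testing.assert_allclose(sel.bic[i], brute, rtol=1e-8)

    def test_infeasible_candidates_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(size=12)
        expr = _expr(rng.normal(size=(3, 12)))
        with pytest.warns(UserWarning, match="skipping candidate"):
            sel = select_K(expr, t, candidates=[0, 10])
        assert sel.candidates == (0,)


class TestFStatistic:
    def test_constant_gene_gives_zero(self):
        y = np.full(20, 3.0)
        F, df1, df2 = f_statistic(y, y, K=0, n=20)
        assert F == 0.0
        assert (df1, df2) == (3, 16)

    def test_noiseless_signal_gives_infinity(self):
        t = np.linspace(0, 1, 30)
        y = 1 + 2 * t
        fit = fit_temporal(_expr(y[None, :]), t, K=0)
        F, _, _ = f_statistic(y, fit.Yhat[0], K=0, n=30)
        assert np.isinf(F)

    def test_null_follows_reference_f_distribution_small_n(self):
        # 2000 noise genes at n=10, K=0 -> F(3, 6)
        rng = np.random.default_rng(6)
        t = rng.uniform(size=10)
        expr = _expr(rng.normal(size=(2000, 10)))
        fit = fit_temporal(expr, t, K=0)
        table = ftest_pvalues(fit, expr)
        ks = stats.kstest(table["F"], stats.f(3, 6).cdf)
        assert ks.pvalue > 0.01


class TestFTest:
    def test_extreme_genes_pinned(self, power_temporal):
        t = power_temporal["axis"].values
        n = t.size
        const = np.full(n, 1.0)
        linear = 1 + t
        expr = _expr(np.vstack([const, linear]))
        table = ftest_pvalues(fit_temporal(expr, t, K=0), expr)
        by_gene = table.set_index("gene_id")
        assert by_gene.loc["g0", "pvalue"] == 1.0
        assert by_gene.loc["g1", "pvalue"] == 0.0

    def test_null_rejection_rate_near_nominal(self, null_temporal):
        p = null_temporal["table"]["pvalue"]
        assert 0.040 <= np.mean(p <= 0.05) <= 0.060

    def test_table_sorted_by_pvalue_then_gene(self, power_temporal):
        table = power_temporal["table"]
        key = list(zip(table["pvalue"], table["gene_id"]))
        assert key == sorted(key)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.1, 0.9], [0.015, 0.15, 0.9]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


@pytest.fixture(scope="module")
def small_power():
    rng = np.random.default_rng(8)
    n = 120
    t = np.sort(rng.uniform(size=n))
    Y = rng.normal(0, 0.5, size=(40, n))
    Y[:5] += 2.0 * np.sin(np.pi * t)  # strong signal genes
    return _expr(Y), t


class TestPermutationTest:
    def test_same_seed_reproducible(self, small_power):
        expr, t = small_power
        a = permutation_test(expr, t, K=0, B=30, seed=11)
        b = permutation_test(expr, t, K=0, B=30, seed=11)
        assert a.equals(b)

    def test_observed_far_above_null_deep_tail(self, small_power):
        expr, t = small_power
        table = permutation_test(expr, t, K=0, B=50, seed=12)
        by_gene = table.set_index("gene_id")
        assert (by_gene.loc[[f"g{i}" for i in range(5)], "pvalue"] < 0.01).all()
        assert (by_gene["mode"] == "permutation").all()

    def test_gamma_mle_recovers_shape_in_aggregate(self):
        # recovery of Gamma(shape=2, rate=1) from B=100 draws
        from pretsa.temporal import _gamma_tail

        rng = np.random.default_rng(13)
        shapes = []
        for _ in range(200):
            draws = rng.gamma(2.0, 1.0, size=100)
            _, shape, rate, method = _gamma_tail(draws, 1.0)
            assert method == "gamma"
            shapes.append(shape)
        assert np.mean(shapes) == pytest.approx(2.0, rel=0.2)

    def test_degenerate_null_falls_back_to_empirical(self):
        from pretsa.temporal import _gamma_tail

        p, shape, rate, method = _gamma_tail(np.ones(20), 2.0)
        assert method == "empirical"
        assert p == pytest.approx(1.0 / 21.0)

    def test_null_axis_keeps_false_positives_low(self, power_temporal):
        expr = _subset(power_temporal["expr"], 200)
        axis = make_null(power_temporal["axis"], seed=14)
        table = permutation_test(expr, axis.values, K=0, B=50, seed=15)
        assert np.mean(table["fdr"] <= 0.05) <= 0.01

    def test_auto_k_keeps_full_data_selection(self, small_power):
        expr, t = small_power
        table = permutation_test(expr, t, candidates=[0, 1, 2], B=20, seed=16)
        sel = select_K(expr, t, candidates=[0, 1, 2])
        by_gene = table.set_index("gene_id").loc[expr.gene_ids]
        np.testing.assert_array_equal(by_gene["K"].to_numpy(), sel.selected_K)


def _subset(expr, m):
    return ExpressionMatrix(expr.Y[:m], expr.gene_ids[:m], expr.cell_ids)
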