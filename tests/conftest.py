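"""Shared fixtures: synthetic study datasets and independent oracles.

Heavy fixtures are session-scoped so the statistical checks reuse one
generated dataset each.  Canonical fixture seeds: 0 for temporal
datasets, 1 for spatial datasets.
"""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from pretsa import (
    SimConfig,
    fit_spatial,
    fit_temporal,
    ftest_pvalues,
    make_groundtruth,
    svg_test,
)

TEMPORAL_SEED = 0
SPATIAL_SEED = 1


def deboor_basis(x: float, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Brute-force Cox-de Boor recursion, independent of scipy.

    Returns all len(knots)-degree-1 basis values at x; the last true
    span is treated as closed so the right boundary is included.
    """
    n_basis = len(knots) - degree - 1

    def N(i: int, p: int) -> float:
        if p == 0:
            if knots[i] <= x < knots[i + 1]:
                return 1.0
            if x == knots[-1] and knots[i] < x <= knots[i + 1]:
                return 1.0
            return 0.0
        left = 0.0
        if knots[i + p] != knots[i]:
            left = (x - knots[i]) / (knots[i + p] - knots[i]) * N(i, p - 1)
        right = 0.0
        if knots[i + p + 1] != knots[i + 1]:
            right = (knots[i + p + 1] - x) / (
                knots[i + p + 1] - knots[i + 1]
            ) * N(i + 1, p - 1)
        return left + right

    return np.array([N(i, degree) for i in range(n_basis)])


def lstsq_oracle(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-gene normal-equations fit, one solve per gene (reference path)."""
    out = np.empty_like(Y)
    for i in range(Y.shape[0]):
        beta, *_ = np.linalg.lstsq(X, Y[i], rcond=None)
        out[i] = X @ beta
    return out


def auprc(truth: np.ndarray, pvalues: np.ndarray) -> float:
    """Area under precision-recall for ranking genes by ascending p."""
    return float(average_precision_score(truth, -np.asarray(pvalues)))


def pvals_in_gene_order(table, gene_ids) -> np.ndarray:
    return table.set_index("gene_id").loc[np.asarray(gene_ids), "pvalue"].to_numpy()


@pytest.fixture(scope="session")
def power_temporal():
    """2000 genes x 500 cells, 10% TVGs with 3-SD smooth signals."""
    cfg = SimConfig(seed=TEMPORAL_SEED, mode="temporal")
    expr, axis, truth = make_groundtruth(cfg)
    fit = fit_temporal(expr, axis.values, K=0)
    table = ftest_pvalues(fit, expr)
    return {"expr": expr, "axis": axis, "truth": truth, "fit": fit,
            "table": table}


@pytest.fixture(scope="session")
def power_spatial():
    """2000 genes x 500 spots, 10% SVGs with 3-SD smooth surfaces."""
    cfg = SimConfig(seed=SPATIAL_SEED, mode="spatial")
    expr, axis, truth = make_groundtruth(cfg)
    fit = fit_spatial(expr, axis.values, K=0)
    table = svg_test(fit, expr)
    return {"expr": expr, "axis": axis, "truth": truth, "fit": fit,
            "table": table}


@pytest.fixture(scope="session")
def null_temporal():
    """2000 pure-noise genes x 200 cells (exact-distribution checks)."""
    cfg = SimConfig(n_cells=200, fraction_variable=0.0, seed=TEMPORAL_SEED,
                    mode="temporal")
    expr, axis, _ = make_groundtruth(cfg)
    fit = fit_temporal(expr, axis.values, K=0)
    table = ftest_pvalues(fit, expr)
    return {"expr": expr, "axis": axis, "fit": fit, "table": table}


@pytest.fixture(scope="session")
def null_spatial():
    """2000 pure-noise genes on a 30 x 30 integer grid."""
    cfg = SimConfig(n_cells=900, fraction_variable=0.0, seed=SPATIAL_SEED,
                    mode="spatial", grid_dims=(30, 30))
    expr, axis, _ = make_groundtruth(cfg)
    fit = fit_spatial(expr, axis.values, K=0)
    table = svg_test(fit, expr)
    return {"expr": expr, "axis": axis, "fit": fit, "table": table}
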