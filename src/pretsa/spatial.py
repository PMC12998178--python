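"""Spatial expression surfaces over 2-D coordinates and SVG testing.

The surface for gene i is a tensor-product cubic B-spline in the two
coordinate axes (marginal terms for each axis plus all pairwise basis
products, (K+4)^2 coefficients including the intercept).  Because the
spot locations are measured rather than inferred, the exact F-test with
df ((K+4)^2 - 1, n - (K+4)^2) is used directly, with no permutation
stage.  K selection mirrors the temporal BIC with penalty (K+4)^2 + 1
over candidates {0..5} by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .basis import spatial_design
from .core import ExpressionMatrix, FitResult, fit_genes_blocked
from .temporal import (
    KSelection,
    _f_stats,
    _fit_mixed_K,
    _result_table,
    bic_from_fit,
)

__all__ = [
    "bic_spatial",
    "select_K_spatial",
    "fit_spatial",
    "svg_test",
]

DEFAULT_K_CANDIDATES_SPATIAL = tuple(range(0, 6))


def bic_spatial(y, yhat, K: int, n: int):
    """BIC of a spatial fit with (K+4)^2 coefficients."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    rss_mean = np.mean((y - yhat) ** 2, axis=-1)
    out = bic_from_fit(rss_mean, (K + 4) ** 2, n)
    return float(out[0]) if out.size == 1 else out


def _feasible_spatial(candidates, n: int) -> list[int]:
    cands = sorted(set(int(k) for k in candidates))
    if not cands:
        raise ValueError("candidate set is empty")
    if any(k < 0 for k in cands):
        raise ValueError("candidate K values must be non-negative")
    feasible = [k for k in cands if n > (k + 4) ** 2]
    skipped = sorted(set(cands) - set(feasible))
    if skipped:
        warnings.warn(
            f"skipping spatial candidate K values {skipped}: n={n} too small",
            stacklevel=3,
        )
    if not feasible:
        raise ValueError("no feasible spatial candidate K for this sample size")
    return feasible


def select_K_spatial(
    expr: ExpressionMatrix,
    S: np.ndarray,
    candidates=DEFAULT_K_CANDIDATES_SPATIAL,
    n_blocks: int = 1,
) -> KSelection:
    """Per-gene BIC selection of the spatial knot count."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    feasible = _feasible_spatial(candidates, n)
    bic = np.empty((expr.n_genes, len(feasible)))
    for c, K in enumerate(feasible):
        design = spatial_design(S, K)
        fit = fit_genes_blocked(expr, design, n_blocks=n_blocks)
        bic[:, c] = bic_from_fit(fit.sigma2, (K + 4) ** 2, n)
    sel = np.asarray(feasible, dtype=int)[np.argmin(bic, axis=1)]
    return KSelection(
        gene_ids=expr.gene_ids, candidates=tuple(feasible), bic=bic, selected_K=sel
    )


def fit_spatial(
    expr: ExpressionMatrix,
    S: np.ndarray,
    K: int = 0,
    candidates=None,
    n_blocks: int = 1,
) -> FitResult:
    """Fit tensor-product surfaces for all genes, shared hat matrix per K."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("S must be an n x 2 coordinate array")
    if expr.n_cells != S.shape[0]:
        raise ValueError("coordinate rows do not match expression columns")
    if candidates is None:
        design = spatial_design(S, K)
        return fit_genes_blocked(expr, design, n_blocks=n_blocks)
    sel = select_K_spatial(expr, S, candidates=candidates, n_blocks=n_blocks)
    return _fit_mixed_K(expr.Y, sel.selected_K, lambda k: spatial_design(S, k),
                        n_blocks=n_blocks)


def svg_test(fit: FitResult, expr: ExpressionMatrix) -> pd.DataFrame:
    """Exact F-test for SVGs: upper tail of F((K+4)^2-1, n-(K+4)^2)."""
    n = fit.n
    K = fit.K_per_gene
    df1 = (K + 4) ** 2 - 1
    df2 = n - (K + 4) ** 2
    if np.any(df2 <= 0):
        raise ValueError("SVG test requires n > (K+4)^2 for every gene")
    F = _f_stats(expr.Y, fit.Yhat, df1.astype(float), df2.astype(float))
    pvalue = stats.f.sf(F, df1, df2)
    return _result_table(expr.gene_ids, K, F, df1, df2, pvalue, "ftest")
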