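"""Temporal expression curves along pseudotime and TVG testing.

For gene i with expression y_ij at pseudotime t_j the model is

    y_ij = beta_i0 + sum_k b_k(t_j) beta_ik + eps_ij,   eps_ij ~ N(0, sigma_i^2)

with b_1..b_{K+3} the cubic B-spline basis on K equidistant internal
knots.  The default fixes K = 0 for every gene; the auto-K variant
selects K per gene over {0..10} by BIC.  Temporal variability is tested
either by the exact F-test (pseudotime treated as fixed) or by a
subsample-permutation procedure whose null F values are summarized by a
fitted Gamma distribution, propagating pseudotime uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import SplineDesign, temporal_design
from .core import ExpressionMatrix, FitResult, fit_genes_blocked

__all__ = [
    "KSelection",
    "bic_temporal",
    "select_K",
    "fit_temporal",
    "f_statistic",
    "ftest_pvalues",
    "bh_adjust",
    "permutation_test",
]

# Residual mean squares are floored before entering logs/denominators so a
# perfect fit yields a finite BIC and the only infinities are the F = +inf
# case (zero residual, non-constant fit), which maps to p = 0.
VAR_FLOOR = 1e-12

DEFAULT_K_CANDIDATES = tuple(range(0, 11))


def bic_from_fit(rss_mean: np.ndarray | float, p: int, n: int) -> np.ndarray | float:
    """Gaussian BIC given the 1/n residual mean square and p coefficients.

    ``n log(rss/n) + (p+1) log n + n + n log 2pi`` -- the +1 counts the
    variance parameter.
    """
    rss_mean = np.maximum(rss_mean, VAR_FLOOR)
    return n * np.log(rss_mean) + (p + 1) * np.log(n) + n + n * np.log(2 * np.pi)


def bic_temporal(y, yhat, K: int, n: int):
    """BIC of a temporal fit with K internal knots (p = K+4 coefficients)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    if y.shape != yhat.shape:
        raise ValueError("y and yhat shapes differ")
    rss_mean = np.mean((y - yhat) ** 2, axis=-1)
    out = bic_from_fit(rss_mean, K + 4, n)
    return float(out[0]) if out.size == 1 else out


@dataclass
class KSelection:
    """Per-gene BIC values over the candidate knot counts."""

    gene_ids: np.ndarray
    candidates: tuple[int, ...]
    bic: np.ndarray  # m x len(candidates)
    selected_K: np.ndarray  # m

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.bic, index=self.gene_ids, columns=[f"K={k}" for k in self.candidates]
        )
        df["selected_K"] = self.selected_K
        return df


def _feasible_candidates(candidates, n: int, min_extra: int = 0) -> list[int]:
    cands = sorted(set(int(k) for k in candidates))
    if not cands:
        raise ValueError("candidate set is empty")
    if any(k < 0 for k in cands):
        raise ValueError("candidate K values must be non-negative")
    feasible = [k for k in cands if n > k + 4 + min_extra]
    skipped = sorted(set(cands) - set(feasible))
    if skipped:
        warnings.warn(
            f"skipping candidate K values {skipped}: n={n} too small", stacklevel=3
        )
    if not feasible:
        raise ValueError("no feasible candidate K for this sample size")
    return feasible


def select_K(
    expr: ExpressionMatrix,
    t: np.ndarray,
    candidates=DEFAULT_K_CANDIDATES,
    n_blocks: int = 1,
) -> KSelection:
    """Choose K per gene by minimizing BIC over the candidate grid.

    One shared design and one fitted matrix per candidate serve all
    genes; ties favor the smaller K (parsimony).
    """
    t = np.asarray(t, dtype=float).ravel()
    n = t.size
    feasible = _feasible_candidates(candidates, n)
    bic = np.empty((expr.n_genes, len(feasible)))
    for c, K in enumerate(feasible):
        design = temporal_design(t, K)
        fit = fit_genes_blocked(expr, design, n_blocks=n_blocks)
        bic[:, c] = bic_from_fit(fit.sigma2, K + 4, n)
    sel = np.asarray(feasible, dtype=int)[np.argmin(bic, axis=1)]
    return KSelection(
        gene_ids=expr.gene_ids, candidates=tuple(feasible), bic=bic, selected_K=sel
    )


def fit_temporal(
    expr: ExpressionMatrix,
    t: np.ndarray,
    K: int = 0,
    candidates=None,
    n_blocks: int = 1,
) -> FitResult:
    """Fit all genes along pseudotime with fixed K or per-gene auto-K.

    With ``candidates`` given, K is selected per gene by BIC and genes
    sharing a K are fitted together against that K's shared design.
    """
    t = np.asarray(t, dtype=float).ravel()
    if expr.n_cells != t.size:
        raise ValueError("pseudotime length does not match expression columns")
    if candidates is None:
        design = temporal_design(t, K)
        return fit_genes_blocked(expr, design, n_blocks=n_blocks)
    sel = select_K(expr, t, candidates=candidates, n_blocks=n_blocks)
    return _fit_mixed_K(expr.Y, sel.selected_K, lambda k: temporal_design(t, k),
                        n_blocks=n_blocks)


def _fit_mixed_K(Y: np.ndarray, K_per_gene: np.ndarray, make_design,
                 n_blocks: int = 1) -> FitResult:
    """Fit gene groups that selected different K, one shared design each."""
    m, n = Y.shape
    Yhat = np.empty_like(Y)
    beta: list[np.ndarray | None] = [None] * m
    sigma2 = np.empty(m)
    designs: dict[int, SplineDesign] = {}
    for k in np.unique(K_per_gene):
        idx = np.flatnonzero(K_per_gene == k)
        design = make_design(int(k))
        designs[int(k)] = design
        sub = fit_genes_blocked(Y[idx], design, n_blocks=n_blocks)
        Yhat[idx] = sub.Yhat
        sigma2[idx] = sub.sigma2
        for i, g in enumerate(idx):
            beta[g] = sub.beta[i]
    return FitResult(Yhat=Yhat, beta=beta, sigma2=sigma2,
                     K_per_gene=np.asarray(K_per_gene, dtype=int), designs=designs)


def _f_stats(Y: np.ndarray, Yhat: np.ndarray, df1: np.ndarray, df2: np.ndarray):
    """Vectorized F statistics: model SS about the gene mean vs residual SS."""
    ybar = Y.mean(axis=1, keepdims=True)
    ss_fit = np.sum((Yhat - ybar) ** 2, axis=1)
    ss_res = np.sum((Y - Yhat) ** 2, axis=1)
    F = np.zeros(Y.shape[0])
    flat = ss_fit <= VAR_FLOOR  # constant fitted curve -> F = 0
    exact = (~flat) & (ss_res <= VAR_FLOOR)  # perfect non-constant fit
    ok = ~flat & ~exact
    F[ok] = (ss_fit[ok] / df1[ok]) / (ss_res[ok] / df2[ok])
    F[exact] = np.inf
    return F


def f_statistic(y, yhat, K: int, n: int) -> tuple[float, int, int]:
    """Single-gene temporal F statistic with df (K+3, n-K-4)."""
    if n <= K + 4:
        raise ValueError("F statistic requires n > K + 4")
    df1, df2 = K + 3, n - K - 4
    y2 = np.asarray(y, dtype=float)[None, :]
    yh2 = np.asarray(yhat, dtype=float)[None, :]
    F = _f_stats(y2, yh2, np.array([df1]), np.array([df2]))[0]
    return float(F), df1, df2


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(stats.false_discovery_control(p, method="bh"), 1.0)


def _result_table(gene_ids, K, F, df1, df2, pvalue, mode, **extra) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "K": np.asarray(K, dtype=int),
            "F": F,
            "df1": np.asarray(df1, dtype=int),
            "df2": np.asarray(df2, dtype=int),
            "pvalue": pvalue,
            "fdr": bh_adjust(pvalue),
            "mode": mode,
        }
    )
    for name, vals in extra.items():
        df[name] = vals
    return df.sort_values(["pvalue", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )


def ftest_pvalues(fit: FitResult, expr: ExpressionMatrix) -> pd.DataFrame:
    """Exact F-test for TVGs: upper tail of F(K+3, n-K-4), BH across genes."""
    n = fit.n
    K = fit.K_per_gene
    df1 = K + 3
    df2 = n - K - 4
    if np.any(df2 <= 0):
        raise ValueError("F-test requires n > K + 4 for every gene")
    F = _f_stats(expr.Y, fit.Yhat, df1.astype(float), df2.astype(float))
    pvalue = stats.f.sf(F, df1, df2)
    return _result_table(expr.gene_ids, K, F, df1, df2, pvalue, "ftest")


def _gamma_tail(null_vals: np.ndarray, f_obs: float):
    """Upper-tail p of f_obs under a Gamma fitted to the null F values.

    Fallbacks when the maximum-likelihood fit is unavailable: method of
    moments, then the empirical tail (count+1)/(B+1).
    """
    B = null_vals.size
    finite = np.all(np.isfinite(null_vals))
    spread = finite and np.std(null_vals) > 0
    shape = rate = np.nan
    if finite and spread and np.all(null_vals > 0):
        try:
            a, _, scale = stats.gamma.fit(null_vals, floc=0)
            if np.isfinite(a) and np.isfinite(scale) and a > 0 and scale > 0:
                shape, rate = a, 1.0 / scale
        except Exception:
            pass
    if not np.isfinite(shape) and finite and spread:
        mean = null_vals.mean()
        var = null_vals.var()
        if mean > 0 and var > 0:
            shape = mean * mean / var
            rate = mean / var
    if np.isfinite(shape):
        if np.isinf(f_obs):
            return 0.0, shape, rate, "gamma"
        return float(stats.gamma.sf(f_obs, shape, scale=1.0 / rate)), shape, rate, (
            "gamma"
        )
    vals = null_vals[np.isfinite(null_vals)]
    p = (np.sum(vals >= f_obs) + 1.0) / (B + 1.0)
    return float(p), np.nan, np.nan, "empirical"


def permutation_test(
    expr: ExpressionMatrix,
    t: np.ndarray,
    K: int = 0,
    candidates=None,
    B: int = 100,
    subsample_frac: float = 0.8,
    infer=None,
    seed: int | None = None,
    n_blocks: int = 1,
    return_null: bool = False,
):
    """TVG test propagating pseudotime uncertainty via subsampled permutations.

    Each of the B replicates subsamples ``floor(subsample_frac * n)``
    cells without replacement, obtains their pseudotime (by default the
    restriction of ``t``; pass ``infer(Y_sub, cell_ids_sub)`` to re-run a
    trajectory method), randomly permutes it, and refits every gene
    against that replicate's single shared design, yielding one null F
    per gene per replicate.  A Gamma distribution fitted per gene to its
    B null values supplies the upper-tail p-value of the observed
    full-data F.  With ``candidates`` given, each gene keeps the K it
    selected on the full data throughout.

    All randomness derives from ``seed`` through per-replicate spawned
    streams, so runs are exactly reproducible.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must lie in (0, 1]")
    t = np.asarray(t, dtype=float).ravel()
    n = t.size
    if expr.n_cells != n:
        raise ValueError("pseudotime length does not match expression columns")

    fit = fit_temporal(expr, t, K=K, candidates=candidates, n_blocks=n_blocks)
    Kg = fit.K_per_gene
    df1 = Kg + 3
    df2 = n - Kg - 4
    if np.any(df2 <= 0):
        raise ValueError("permutation test requires n > K + 4 for every gene")
    F_obs = _f_stats(expr.Y, fit.Yhat, df1.astype(float), df2.astype(float))

    n_sub = int(np.floor(subsample_frac * n))
    if n_sub <= int(Kg.max()) + 4:
        raise ValueError("subsample too small for the selected K")
    null_F = np.empty((expr.n_genes, B))
    streams = np.random.SeedSequence(seed).spawn(B)
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        if infer is None:
            t_sub = t[idx]
        else:
            t_sub = np.asarray(
                infer(expr.Y[:, idx], expr.cell_ids[idx]), dtype=float
            ).ravel()
        t_null = t_sub[rng.permutation(n_sub)]
        for k in np.unique(Kg):
            gidx = np.flatnonzero(Kg == k)
            design = temporal_design(t_null, int(k))
            sub = fit_genes_blocked(expr.Y[np.ix_(gidx, idx)], design,
                                    n_blocks=n_blocks)
            null_F[gidx, b] = _f_stats(
                expr.Y[np.ix_(gidx, idx)],
                sub.Yhat,
                np.full(gidx.size, k + 3.0),
                np.full(gidx.size, n_sub - k - 4.0),
            )

    m = expr.n_genes
    pvalue = np.empty(m)
    shape = np.empty(m)
    rate = np.empty(m)
    for i in range(m):
        p_i, a_i, r_i, method = _gamma_tail(null_F[i], F_obs[i])
        if method == "empirical":
            warnings.warn(
                f"gene {expr.gene_ids[i]}: degenerate null F values; "
                "using empirical tail",
                stacklevel=2,
            )
        pvalue[i] = p_i
        shape[i] = a_i
        rate[i] = r_i

    table = _result_table(
        expr.gene_ids, Kg, F_obs, df1, df2, pvalue, "permutation",
        gamma_shape=shape, gamma_rate=rate,
    )
    if return_null:
        return table, null_F
    return table
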