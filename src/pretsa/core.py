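"""Core data containers and the shared-factorization least-squares engine.

All genes share one design matrix, so the expensive part of the fit --
the orthogonal factorization of X -- is computed once and applied to
every gene's expression row.  Fitted values are the projection
``Yhat = Y @ H`` with ``H = X (X'X)^-1 X'``, realized through a thin QR
factorization rather than by materializing H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .basis import SplineDesign

__all__ = [
    "ExpressionMatrix",
    "AxisValues",
    "FitResult",
    "DesignFactor",
    "fit_genes",
    "fit_genes_blocked",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of library-size-normalized log expression."""

    Y: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-dimensional (genes x cells)")
        m, n = self.Y.shape
        if m < 1:
            raise ValueError("no genes")
        if n < 2:
            raise ValueError("need at least 2 cells")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length does not match Y rows")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match Y columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.Y.shape[0]

    @property
    def n_cells(self) -> int:
        return self.Y.shape[1]


@dataclass
class AxisValues:
    """Per-cell pseudotime (n,) or per-spot 2-D coordinates (n, 2)."""

    kind: str  # "temporal" | "spatial"
    values: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.kind not in ("temporal", "spatial"):
            raise ValueError("kind must be 'temporal' or 'spatial'")
        if self.kind == "temporal" and self.values.ndim != 1:
            raise ValueError("temporal axis values must be 1-dimensional")
        if self.kind == "spatial" and (
            self.values.ndim != 2 or self.values.shape[1] != 2
        ):
            raise ValueError("spatial axis values must be n x 2")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match axis values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("axis values contain non-finite entries")


@dataclass
class FitResult:
    """Per-gene least-squares fits against one or more shared designs.

    ``beta`` is a list of per-gene coefficient vectors (lengths differ
    when genes select different K).  ``sigma2`` is the 1/n residual
    variance used by the BIC.
    """

    Yhat: np.ndarray
    beta: list[np.ndarray]
    sigma2: np.ndarray
    K_per_gene: np.ndarray
    designs: dict[int, SplineDesign] = field(repr=False, default_factory=dict)

    @property
    def n(self) -> int:
        return self.Yhat.shape[1]


class DesignFactor:
    """Thin-QR factorization of a design matrix, reusable across genes.

    Rank deficiency is detected from the R diagonal; the solve then
    falls back to the pseudoinverse (minimum-norm coefficients) with a
    warning, while fitted values remain the orthogonal projection.
    """

    def __init__(self, design: SplineDesign):
        self.design = design
        X = design.X
        self.Q, self.R = np.linalg.qr(X, mode="reduced")
        diag = np.abs(np.diag(self.R))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        self.rank_deficient = bool(np.any(diag <= tol))
        if self.rank_deficient:
            warnings.warn(
                "rank-deficient design matrix; using pseudoinverse", stacklevel=2
            )
            self._pinv = np.linalg.pinv(X)

    def fit_block(self, Yb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (Yhat_block, coef_block) for a block of gene rows.

        Each gene is solved independently so results are bitwise
        identical for any block partition of the gene panel.
        """
        mb = Yb.shape[0]
        Yhat = np.empty_like(Yb)
        coef = np.empty((mb, self.Q.shape[1]))
        X = self.design.X
        for i in range(mb):
            if self.rank_deficient:
                # Q from unpivoted QR over-spans a rank-deficient X, so
                # project through the minimum-norm coefficients instead
                coef[i] = self._pinv @ Yb[i]
                Yhat[i] = X @ coef[i]
            else:
                c = self.Q.T @ Yb[i]
                Yhat[i] = self.Q @ c
                coef[i] = linalg.solve_triangular(self.R, c)
        return Yhat, coef


def fit_genes_blocked(
    Y: ExpressionMatrix | np.ndarray,
    design: SplineDesign,
    n_blocks: int = 10,
) -> FitResult:
    """Fit all genes against one shared design, in gene blocks.

    The design is factorized once; blocks only bound the size of the
    intermediate fitted matrices (peak extra storage ~ (m/n_blocks) x n),
    matching the memory strategy used for very large gene panels.
    Output is identical to ``fit_genes`` for any ``n_blocks``.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    Ymat = Y.Y if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)
    m, n = Ymat.shape
    if n != design.n:
        raise ValueError(
            f"expression has {n} cells but design has {design.n} rows"
        )
    fac = DesignFactor(design)
    Yhat = np.empty_like(Ymat)
    beta: list[np.ndarray] = []
    bounds = np.array_split(np.arange(m), min(n_blocks, m))
    for idx in bounds:
        if idx.size == 0:
            continue
        yh, coef = fac.fit_block(Ymat[idx])
        Yhat[idx] = yh
        beta.extend(coef)
    resid = Ymat - Yhat
    sigma2 = np.mean(resid * resid, axis=1)
    K = np.full(m, design.K, dtype=int)
    return FitResult(Yhat=Yhat, beta=beta, sigma2=sigma2, K_per_gene=K,
                     designs={design.K: design})


def fit_genes(Y: ExpressionMatrix | np.ndarray, design: SplineDesign) -> FitResult:
    """Fit every gene by least squares against one shared design matrix."""
    return fit_genes_blocked(Y, design, n_blocks=1)


def align_axis(
    expr: ExpressionMatrix, axis: AxisValues
) -> tuple[ExpressionMatrix, AxisValues]:
    """Reorder expression columns and axis rows to their common cells.

    Cells present on only one side are dropped (count logged via a
    warning); the output order follows the expression matrix.
    """
    axis_pos = {c: i for i, c in enumerate(axis.cell_ids)}
    keep = [j for j, c in enumerate(expr.cell_ids) if c in axis_pos]
    if not keep:
        raise ValueError("no cells in common between expression and axis values")
    dropped = (expr.n_cells - len(keep)) + (len(axis.cell_ids) - len(keep))
    if dropped:
        warnings.warn(f"dropped {dropped} cells missing from one input", stacklevel=2)
    order = [axis_pos[expr.cell_ids[j]] for j in keep]
    expr2 = ExpressionMatrix(
        Y=expr.Y[:, keep],
        gene_ids=expr.gene_ids,
        cell_ids=expr.cell_ids[keep],
    )
    axis2 = AxisValues(
        kind=axis.kind,
        values=axis.values[order],
        cell_ids=axis.cell_ids[order],
    )
    return expr2, axis2
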