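"""Optional pre-aggregation of cells into temporal or spatial bins.

Pseudotime is partitioned into equal-width intervals (default 100) or
spatial coordinates into an evenly spaced grid (default 100 x 100);
expression is averaged per gene within each occupied bin, and the fit
then treats bins as the observational units.  Note that downstream df
and BIC formulas use the number of occupied bins, so p-values are not
directly comparable with unbinned runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AxisValues, ExpressionMatrix

__all__ = ["BinnedData", "bin_temporal", "bin_spatial"]


@dataclass
class BinnedData:
    """Bin-averaged expression with bin centers, counts and cell mapping."""

    Yb: np.ndarray  # m x n_b
    bin_centers: np.ndarray  # n_b (temporal) or n_b x 2 (spatial)
    bin_counts: np.ndarray  # n_b
    mapping: np.ndarray  # original cell -> occupied-bin index

    @property
    def n_bins(self) -> int:
        return self.Yb.shape[1]

    def as_expression(self, gene_ids) -> tuple[ExpressionMatrix, AxisValues]:
        """Repackage bins as a pseudo expression matrix + axis for fitting."""
        ids = np.array([f"bin{i}" for i in range(self.n_bins)], dtype=object)
        kind = "temporal" if self.bin_centers.ndim == 1 else "spatial"
        expr = ExpressionMatrix(Y=self.Yb, gene_ids=np.asarray(gene_ids),
                                cell_ids=ids)
        axis = AxisValues(kind=kind, values=self.bin_centers, cell_ids=ids)
        return expr, axis


def _mean_by_bin(Y: np.ndarray, raw_bin: np.ndarray, n_total_bins: int):
    counts = np.bincount(raw_bin, minlength=n_total_bins)
    occupied = np.flatnonzero(counts > 0)
    if occupied.size < 2:
        raise ValueError("degenerate binning: fewer than 2 occupied bins")
    # dense index over occupied bins only; empty bins are dropped
    dense = np.full(n_total_bins, -1, dtype=int)
    dense[occupied] = np.arange(occupied.size)
    mapping = dense[raw_bin]
    sums = np.zeros((Y.shape[0], occupied.size))
    np.add.at(sums.T, mapping, Y.T)
    Yb = sums / counts[occupied]
    return Yb, occupied, counts[occupied], mapping


def bin_temporal(Y: ExpressionMatrix | np.ndarray, t, n_bins: int = 100) -> BinnedData:
    """Average expression within equal-width pseudotime intervals.

    Intervals are right-closed, except the first which also includes its
    left edge; bin centers are interval midpoints; empty bins dropped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    Ymat = Y.Y if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if Ymat.shape[1] != t.size:
        raise ValueError("pseudotime length does not match expression columns")
    lo, hi = t.min(), t.max()
    if lo == hi:
        raise ValueError("degenerate axis: all pseudotime values identical")
    edges = np.linspace(lo, hi, n_bins + 1)
    # right-closed: t in (edges[i], edges[i+1]] -> bin i; lo falls in bin 0
    raw = np.digitize(t, edges[1:-1], right=True)
    Yb, occupied, counts, mapping = _mean_by_bin(Ymat, raw, n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return BinnedData(Yb=Yb, bin_centers=centers[occupied], bin_counts=counts,
                      mapping=mapping)


def bin_spatial(
    Y: ExpressionMatrix | np.ndarray, S, grid: tuple[int, int] = (100, 100)
) -> BinnedData:
    """Average expression within an evenly spaced 2-D grid of coordinates.

    Grid cells are left-closed along each axis (a spot exactly on an
    interior edge joins the higher-index cell); the last cell includes
    the maximum.  Centers are grid-cell centers; empty cells dropped.
    """
    gx, gy = int(grid[0]), int(grid[1])
    if gx < 2 or gy < 2:
        raise ValueError("grid dimensions must be >= 2")
    Ymat = Y.Y if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("S must be an n x 2 coordinate array")
    if Ymat.shape[1] != S.shape[0]:
        raise ValueError("coordinate rows do not match expression columns")
    idx2 = []
    centers_1d = []
    for ax, g in ((0, gx), (1, gy)):
        v = S[:, ax]
        lo, hi = v.min(), v.max()
        if lo == hi:
            raise ValueError("degenerate axis: all coordinates identical")
        edges = np.linspace(lo, hi, g + 1)
        # left-closed: v in [edges[i], edges[i+1]) -> cell i; hi in last cell
        ix = np.minimum(np.digitize(v, edges[1:-1], right=False), g - 1)
        idx2.append(ix)
        centers_1d.append((edges[:-1] + edges[1:]) / 2.0)
    raw = idx2[0] * gy + idx2[1]
    Yb, occupied, counts, mapping = _mean_by_bin(Ymat, raw, gx * gy)
    cx = centers_1d[0][occupied // gy]
    cy = centers_1d[1][occupied % gy]
    return BinnedData(Yb=Yb, bin_centers=np.column_stack([cx, cy]),
                      bin_counts=counts, mapping=mapping)
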