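"""Cubic B-spline bases and design matrices shared across genes.

The regression design depends only on the axis values (pseudotime or
2-D spatial coordinates), never on expression, so one design matrix --
and hence one hat matrix -- serves every gene simultaneously.

Conventions
-----------
* ``K`` counts *equidistant internal knots*; boundary knots sit at the
  observed min/max of the axis with multiplicity 4 (clamped cubic
  spline), giving ``K + 4`` raw basis functions that sum to one.
* The first raw basis function is dropped for identifiability next to
  an explicit intercept column, leaving ``K + 3`` basis columns.  The
  column space of ``[1 | basis]`` equals that of the full raw basis.
* Evaluation points outside the boundary interval are clamped to it,
  so a design built on one set of axis values can be re-used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "KnotSpec",
    "SplineDesign",
    "make_knots",
    "bspline_basis",
    "temporal_design",
    "spatial_design",
]

DEGREE = 3  # cubic


@dataclass(frozen=True)
class KnotSpec:
    """Placement of K equidistant internal knots on a bounded axis."""

    K: int
    boundary_lo: float
    boundary_hi: float
    internal_knots: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be a non-negative integer")
        if not self.boundary_lo < self.boundary_hi:
            raise ValueError("degenerate axis: boundary_lo must be < boundary_hi")
        if len(self.internal_knots) != self.K:
            raise ValueError("internal_knots length must equal K")

    @property
    def full_knots(self) -> np.ndarray:
        """Clamped knot vector: boundaries repeated degree+1 times."""
        return np.concatenate(
            [
                np.repeat(self.boundary_lo, DEGREE + 1),
                np.asarray(self.internal_knots, dtype=float),
                np.repeat(self.boundary_hi, DEGREE + 1),
            ]
        )

    @property
    def n_basis(self) -> int:
        """Number of basis columns after dropping the first raw function."""
        return self.K + DEGREE


@dataclass(frozen=True)
class SplineDesign:
    """An n x p design matrix plus the knot metadata that produced it.

    ``column_roles`` tags each column as ``intercept``, ``marginal-axis1``,
    ``marginal-axis2`` or ``interaction`` so coefficient vectors can be
    interpreted without re-deriving the layout.
    """

    X: np.ndarray
    axis_kind: str  # "temporal" | "spatial"
    knots: tuple[KnotSpec, ...]
    column_roles: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return self.knots[0].K


def make_knots(values, K: int) -> KnotSpec:
    """Build K equidistant internal knots over the observed range of *values*.

    Internal knot i (0-based) sits at ``lo + (i+1) * (hi-lo) / (K+1)``.
    """
    if K < 0:
        raise ValueError("K must be a non-negative integer")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to define an axis")
    if not np.all(np.isfinite(v)):
        raise ValueError("axis values must be finite")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError("degenerate axis: all values identical")
    internal = lo + np.arange(1, K + 1) * (hi - lo) / (K + 1)
    return KnotSpec(K=K, boundary_lo=lo, boundary_hi=hi, internal_knots=internal)


def bspline_basis(values, knots: KnotSpec) -> np.ndarray:
    """Evaluate the K+3 cubic B-spline basis columns at *values*.

    Returns the full clamped basis of K+4 functions with the first one
    dropped; rows therefore sum to ``1 - B_0(t)``.  Out-of-range points
    are clamped to the boundary interval.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no evaluation points")
    x = np.clip(v, knots.boundary_lo, knots.boundary_hi)
    full = BSpline.design_matrix(x, knots.full_knots, DEGREE).toarray()
    return full[:, 1:]


def temporal_design(t, K: int) -> SplineDesign:
    """Intercept plus K+3 basis columns evaluated at pseudotime t (p = K+4)."""
    t = np.asarray(t, dtype=float).ravel()
    knots = make_knots(t, K)
    n = t.size
    if n <= K + 4:
        warnings.warn(
            f"saturated or under-determined fit: n={n} <= p={K + 4}",
            stacklevel=2,
        )
    B = bspline_basis(t, knots)
    X = np.column_stack([np.ones(n), B])
    roles = ("intercept",) + ("marginal-axis1",) * knots.n_basis
    return SplineDesign(X=X, axis_kind="temporal", knots=(knots,), column_roles=roles)


def spatial_design(S, K: int) -> SplineDesign:
    """Tensor-product design over 2-D coordinates (p = (K+4)^2).

    Column order: intercept, K+3 marginal bases for axis 1, K+3 marginal
    bases for axis 2, then the (K+3)^2 products b1_{k1} * b2_{k2} with
    k1 varying slowest.  Each axis gets its own knots from its own
    observed range, so the fit is invariant to axis-wise rescaling.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("S must be an n x 2 coordinate array")
    n = S.shape[0]
    k1 = make_knots(S[:, 0], K)
    k2 = make_knots(S[:, 1], K)
    B1 = bspline_basis(S[:, 0], k1)
    B2 = bspline_basis(S[:, 1], k2)
    p = (K + 4) ** 2
    if n <= p:
        warnings.warn(
            f"saturated or under-determined fit: n={n} <= p={p}", stacklevel=2
        )
    nb = k1.n_basis
    # interactions: k1 outer, k2 inner -> column (k1*nb + k2)
    inter = (B1[:, :, None] * B2[:, None, :]).reshape(n, nb * nb)
    X = np.column_stack([np.ones(n), B1, B2, inter])
    roles = (
        ("intercept",)
        + ("marginal-axis1",) * nb
        + ("marginal-axis2",) * nb
        + ("interaction",) * (nb * nb)
    )
    return SplineDesign(X=X, axis_kind="spatial", knots=(k1, k2), column_roles=roles)
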