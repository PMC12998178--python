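"""Synthetic data generators for temporal and spatial expression studies.

Three families of inputs are produced, all pure functions of their
arguments and a seed:

* ground-truth datasets: Gaussian log-expression with a stated fraction
  of genes carrying a smooth mean signal along pseudotime or over the
  tissue plane, scaled in residual-SD units, with truth labels for
  precision-recall evaluation;
* scalability datasets: columns resampled with replacement from a base
  matrix, paired with integer pseudotime 1..n or a full integer grid of
  spot locations;
* null datasets: the original data with axis values randomly permuted
  across cells.

The generator emulates the evaluation structure of copula-based count
simulators (gene count, variable fraction, ranking metric) but works
directly on the Gaussian log-expression scale the model fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AxisValues, ExpressionMatrix

__all__ = [
    "SimConfig",
    "make_groundtruth",
    "make_null",
    "resample_scaling_temporal",
    "resample_scaling_spatial",
    "overlap_proportion",
]

TEMPORAL_FAMILIES = ("spline-bump", "linear", "sinusoid")
SPATIAL_FAMILIES = ("gaussian-blob", "gradient", "stripe")


@dataclass
class SimConfig:
    """Study conditions for a ground-truth dataset.

    ``effect_size`` is the peak-to-trough amplitude of the mean signal
    in residual-SD units; ``fraction_variable`` of the genes carry it.
    """

    n_genes: int = 2000
    n_cells: int = 500
    fraction_variable: float = 0.10
    effect_size: float = 3.0
    noise_sd: float = 0.5
    seed: int = 0
    mode: str = "temporal"  # "temporal" | "spatial"
    grid_dims: tuple[int, int] | None = None  # spatial spots on a grid if set
    signal_families: tuple[str, ...] = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_variable <= 1.0:
            raise ValueError("fraction_variable must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.mode not in ("temporal", "spatial"):
            raise ValueError("mode must be 'temporal' or 'spatial'")
        if self.signal_families is None:
            self.signal_families = (
                TEMPORAL_FAMILIES if self.mode == "temporal" else SPATIAL_FAMILIES
            )


def _temporal_signal(u: np.ndarray, family: str, rng: np.random.Generator):
    """Smooth unit-amplitude mean profile over u in [0, 1]."""
    if family == "spline-bump":
        c = rng.uniform(0.3, 0.7)
        w = rng.uniform(0.1, 0.2)
        f = np.exp(-((u - c) ** 2) / (2 * w * w))
    elif family == "linear":
        f = u if rng.random() < 0.5 else -u
    elif family == "sinusoid":
        freq = rng.uniform(0.5, 1.0)  # at most one full period: stays smooth
        phase = rng.uniform(0, 2 * np.pi)
        f = np.sin(2 * np.pi * freq * u + phase)
    else:
        raise ValueError(f"unknown temporal signal family: {family}")
    span = f.max() - f.min()
    return (f - f.mean()) / span


def _spatial_signal(u1, u2, family: str, rng: np.random.Generator):
    if family == "gaussian-blob":
        c1, c2 = rng.uniform(0.25, 0.75, size=2)
        w = rng.uniform(0.15, 0.3)
        f = np.exp(-(((u1 - c1) ** 2) + (u2 - c2) ** 2) / (2 * w * w))
    elif family == "gradient":
        theta = rng.uniform(0, 2 * np.pi)
        f = np.cos(theta) * u1 + np.sin(theta) * u2
    elif family == "stripe":
        theta = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.5, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        f = np.sin(2 * np.pi * freq * (np.cos(theta) * u1 + np.sin(theta) * u2)
                   + phase)
    else:
        raise ValueError(f"unknown spatial signal family: {family}")
    span = f.max() - f.min()
    return (f - f.mean()) / span


def make_groundtruth(cfg: SimConfig):
    """Generate (expression, axis, truth) with labelled variable genes.

    The first ``round(fraction_variable * n_genes)`` genes carry a
    smooth mean signal of amplitude ``effect_size * noise_sd``; all
    genes get iid Gaussian noise of sd ``noise_sd`` on top of a random
    constant baseline.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    if cfg.mode == "temporal":
        t = np.sort(rng.uniform(0.0, 1.0, size=n))
        axis_vals = t
        u = (t,)
    else:
        if cfg.grid_dims is not None:
            gx, gy = cfg.grid_dims
            xs, ys = np.meshgrid(np.arange(1, gx + 1), np.arange(1, gy + 1),
                                 indexing="ij")
            S = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
            if S.shape[0] != n:
                raise ValueError("grid_dims product must equal n_cells")
        else:
            S = rng.uniform(0.0, 1.0, size=(n, 2))
        axis_vals = S
        lo = S.min(axis=0)
        span = S.max(axis=0) - lo
        u = ((S[:, 0] - lo[0]) / span[0], (S[:, 1] - lo[1]) / span[1])

    n_var = int(round(cfg.fraction_variable * cfg.n_genes))
    truth = np.zeros(cfg.n_genes, dtype=bool)
    truth[:n_var] = True
    amplitude = cfg.effect_size * cfg.noise_sd

    baselines = rng.uniform(0.5, 3.0, size=cfg.n_genes)
    Y = np.empty((cfg.n_genes, n))
    for i in range(cfg.n_genes):
        mu = baselines[i]
        if truth[i]:
            family = cfg.signal_families[i % len(cfg.signal_families)]
            if cfg.mode == "temporal":
                mu = mu + amplitude * _temporal_signal(u[0], family, rng)
            else:
                mu = mu + amplitude * _spatial_signal(u[0], u[1], family, rng)
        Y[i] = mu + rng.normal(0.0, cfg.noise_sd, size=n)

    gene_ids = np.array([f"gene{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    cell_ids = np.array([f"cell{j:05d}" for j in range(n)], dtype=object)
    expr = ExpressionMatrix(Y=Y, gene_ids=gene_ids, cell_ids=cell_ids)
    axis = AxisValues(kind=cfg.mode, values=axis_vals, cell_ids=cell_ids)
    return expr, axis, truth


def make_null(axis: AxisValues, seed: int | None = None) -> AxisValues:
    """Randomly permute axis values across cells; expression untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(axis.values.shape[0])
    return AxisValues(kind=axis.kind, values=axis.values[perm],
                      cell_ids=axis.cell_ids)


def resample_scaling_temporal(
    base: ExpressionMatrix, n_target: int, seed: int | None = None
):
    """Scalability dataset: resampled cells with integer pseudotime 1..n."""
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, base.n_cells, size=n_target)
    cell_ids = np.array([f"cell{j:07d}" for j in range(n_target)], dtype=object)
    expr = ExpressionMatrix(Y=base.Y[:, cols], gene_ids=base.gene_ids,
                            cell_ids=cell_ids)
    t = np.arange(1, n_target + 1, dtype=float)
    return expr, AxisValues(kind="temporal", values=t, cell_ids=cell_ids)


def resample_scaling_spatial(
    base: ExpressionMatrix, grid: tuple[int, int], seed: int | None = None
):
    """Scalability dataset: resampled spots on the full integer grid i x j."""
    gi, gj = int(grid[0]), int(grid[1])
    if gi < 1 or gj < 1:
        raise ValueError("grid dimensions must be >= 1")
    n_target = gi * gj
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, base.n_cells, size=n_target)
    xs, ys = np.meshgrid(np.arange(1, gi + 1), np.arange(1, gj + 1), indexing="ij")
    S = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    cell_ids = np.array([f"spot{j:07d}" for j in range(n_target)], dtype=object)
    expr = ExpressionMatrix(Y=base.Y[:, cols], gene_ids=base.gene_ids,
                            cell_ids=cell_ids)
    return expr, AxisValues(kind="spatial", values=S, cell_ids=cell_ids)


def overlap_proportion(rank_a, rank_b, L: int) -> float:
    """|top-L(a) intersect top-L(b)| / L for two ordered gene rankings."""
    if L <= 0:
        raise ValueError("L must be positive")
    a = list(rank_a)
    b = list(rank_b)
    if L > min(len(a), len(b)):
        raise ValueError("L exceeds ranking length")
    return len(set(a[:L]) & set(b[:L])) / L
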