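"""Readers and writers for the supported file dialects.

Expression matrices travel either as dense delimited text (gene rows,
header of cell ids, tab or comma sniffed from the header line) or as
Matrix Market ``.mtx`` with two sidecar text files, ``<path>.genes.txt``
and ``<path>.cells.txt``, one id per line; MTX rows are genes and
columns are cells, enforced by checking each sidecar length against the
matrix dimensions.  Axis tables are headered TSV: (cell_id, pseudotime)
or (cell_id, x, y).  Result tables are TSV with a fixed column order
and empty fields (never '.') for missing values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core import AxisValues, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_pseudotime",
    "read_coordinates",
    "write_axis",
    "write_result_table",
    "write_manifest",
]

RESULT_COLUMNS = ["gene_id", "K", "F", "df1", "df2", "pvalue", "fdr", "mode"]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_ids(path: Path, what: str) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing {what} sidecar file: {path}")
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return np.asarray(ids, dtype=object)


def read_expression(path, dialect: str | None = None) -> ExpressionMatrix:
    """Load a genes x cells matrix from dense text or MTX + id sidecars."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "mtx" if path.suffix == ".mtx" else "dense"
    if dialect == "mtx":
        M = spio.mmread(path)
        if sparse.issparse(M):
            M = M.toarray()
        M = np.asarray(M, dtype=float)
        genes = _read_ids(path.with_suffix(path.suffix + ".genes.txt"), "gene")
        cells = _read_ids(path.with_suffix(path.suffix + ".cells.txt"), "cell")
        if len(genes) != M.shape[0]:
            raise ValueError(
                f"gene sidecar {path}.genes.txt has {len(genes)} ids but the "
                f"matrix has {M.shape[0]} rows"
            )
        if len(cells) != M.shape[1]:
            raise ValueError(
                f"cell sidecar {path}.cells.txt has {len(cells)} ids but the "
                f"matrix has {M.shape[1]} columns"
            )
        return ExpressionMatrix(Y=M, gene_ids=genes, cell_ids=cells)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError("no genes in expression file")
    try:
        Y = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression entries in {path}: {exc}") from exc
    if np.isnan(Y).any():
        raise ValueError("missing expression values are not supported")
    return ExpressionMatrix(
        Y=Y,
        gene_ids=df.index.to_numpy(dtype=object),
        cell_ids=df.columns.to_numpy(dtype=object),
    )


def write_expression(expr: ExpressionMatrix, path, dialect: str | None = None,
                     Y: np.ndarray | None = None) -> None:
    """Write a matrix in the chosen dialect (``Y`` overrides the values,
    e.g. to emit fitted values with the original ids)."""
    path = Path(path)
    if dialect is None:
        dialect = "mtx" if path.suffix == ".mtx" else "dense"
    mat = expr.Y if Y is None else np.asarray(Y, dtype=float)
    if dialect == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(mat))
        path.with_suffix(path.suffix + ".genes.txt").write_text(
            "\n".join(map(str, expr.gene_ids)) + "\n"
        )
        path.with_suffix(path.suffix + ".cells.txt").write_text(
            "\n".join(map(str, expr.cell_ids)) + "\n"
        )
        return
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.DataFrame(mat, index=expr.gene_ids, columns=expr.cell_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_pseudotime(path) -> AxisValues:
    """Read a (cell_id, pseudotime) delimited table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("pseudotime table needs columns (cell_id, pseudotime)")
    cells = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    t = df.iloc[:, 1].to_numpy(dtype=float)
    return AxisValues(kind="temporal", values=t, cell_ids=cells)


def read_coordinates(path) -> AxisValues:
    """Read a (cell_id, x, y) delimited table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    if df.shape[1] < 3:
        raise ValueError("coordinate table needs columns (cell_id, x, y)")
    cells = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    S = df.iloc[:, 1:3].to_numpy(dtype=float)
    return AxisValues(kind="spatial", values=S, cell_ids=cells)


def write_axis(axis: AxisValues, path) -> None:
    path = Path(path)
    if axis.kind == "temporal":
        df = pd.DataFrame({"cell_id": axis.cell_ids, "pseudotime": axis.values})
    else:
        df = pd.DataFrame(
            {"cell_id": axis.cell_ids, "x": axis.values[:, 0],
             "y": axis.values[:, 1]}
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_result_table(table: pd.DataFrame, path) -> None:
    """Write a TVG/SVG result table as TSV with fixed leading columns."""
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(Path(path), sep="\t", index=False, na_rep="")


def write_manifest(settings: dict, path) -> None:
    """Persist resolved run settings (no timestamps: runs stay byte-stable)."""
    from . import __version__

    payload = {"package": "pretsa", "version": __version__, **settings}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=str) + "\n")
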