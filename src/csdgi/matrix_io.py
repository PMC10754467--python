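"""Expression-matrix container and plain-text readers/writers.

The internal convention throughout the package is cells x genes: ``X[i, g]``
is the (log-scale) expression of gene ``g`` in cell ``i``.  Files may store
either orientation; readers normalize at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

Orientation = Literal["genes_in_rows", "cells_in_rows"]

__all__ = [
    "ExpressionMatrix",
    "CellAnnotation",
    "read_dense_matrix",
    "write_dense_matrix",
    "read_mtx",
    "write_mtx",
    "write_gene_table",
    "read_cell_annotation",
    "write_cell_annotation",
]


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValueError(f"duplicate {what} name: {name!r}")
        seen.add(name)


@dataclass
class ExpressionMatrix:
    """Non-negative log-scale expression values for m cells by n genes."""

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = [str(g).strip() for g in self.gene_names]
        self.cell_ids = [str(c).strip() for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes array")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("matrix must have at least one cell and one gene")
        if len(self.gene_names) != n:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {n} gene columns"
            )
        if len(self.cell_ids) != m:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {m} cell rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            i, g = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_names[g]!r}: {self.values[i, g]}"
            )
        _check_unique(self.gene_names, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: j for j, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], list(genes), list(self.cell_ids))

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return ExpressionMatrix(
            self.values[idx], list(self.gene_names), [self.cell_ids[i] for i in idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_names)


@dataclass
class CellAnnotation:
    """Per-cell labels: tumor/nontumor groups or integer cluster indices."""

    cell_ids: list[str]
    group: list

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.group):
            raise ValueError("cell_ids and group must have equal length")
        _check_unique(self.cell_ids, "cell")

    def aligned_to(self, X: ExpressionMatrix) -> np.ndarray:
        """Return group labels reordered to match ``X.cell_ids``."""
        lookup = dict(zip(self.cell_ids, self.group))
        missing = [c for c in X.cell_ids if c not in lookup]
        if missing:
            raise KeyError(f"cells without annotation: {missing[:5]}")
        return np.asarray([lookup[c] for c in X.cell_ids])


def _orient_to_cells_by_genes(df: pd.DataFrame, orientation: Orientation) -> pd.DataFrame:
    if orientation == "genes_in_rows":
        return df.T
    if orientation == "cells_in_rows":
        return df
    raise ValueError(f"unknown orientation {orientation!r}")


def read_dense_matrix(
    path: str | Path,
    orientation: Orientation = "genes_in_rows",
    delimiter: str = "\t",
    log1p: bool = False,
) -> ExpressionMatrix:
    """Read a delimited matrix with a header row and a leading name column.

    ``orientation`` declares what the file rows are; the result is always
    cells x genes.  Values must parse as finite non-negative reals; the
    optional ``log1p`` applies log(1+x) for matrices still on a linear scale.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        bad = _locate_bad_cell(df)
        where = f" at row {bad[0]!r}, column {bad[1]!r}" if bad else ""
        raise ValueError(f"malformed numeric value in {path}{where}") from exc
    df = _orient_to_cells_by_genes(df, orientation)
    values = df.to_numpy(dtype=float)
    if log1p:
        values = np.log1p(values)
    return ExpressionMatrix(values, [str(c) for c in df.columns], [str(i) for i in df.index])


def _locate_bad_cell(df: pd.DataFrame):
    for row_label, row in df.iterrows():
        for col_label, cell in row.items():
            try:
                float(cell)
            except (TypeError, ValueError):
                return row_label, col_label
    return None


def write_dense_matrix(
    path: str | Path,
    X: ExpressionMatrix,
    orientation: Orientation = "genes_in_rows",
    delimiter: str = "\t",
) -> None:
    df = X.to_frame()
    if orientation == "genes_in_rows":
        df = df.T
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def _read_names(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    orientation: Orientation = "genes_in_rows",
) -> ExpressionMatrix:
    """Read a Matrix Market coordinate file with one-name-per-line sidecars."""
    mat = spio.mmread(str(matrix_path))
    mat = sparse.coo_matrix(mat).toarray()
    genes = _read_names(genes_path)
    cells = _read_names(cells_path)
    if orientation == "genes_in_rows":
        mat = mat.T
    m, n = mat.shape
    if len(genes) != n:
        raise ValueError(
            f"gene sidecar has {len(genes)} names but matrix has {n} genes"
        )
    if len(cells) != m:
        raise ValueError(
            f"cell sidecar has {len(cells)} names but matrix has {m} cells"
        )
    return ExpressionMatrix(mat, genes, cells)


def write_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    X: ExpressionMatrix,
    orientation: Orientation = "genes_in_rows",
) -> None:
    mat = sparse.coo_matrix(X.values if orientation == "cells_in_rows" else X.values.T)
    spio.mmwrite(str(matrix_path), mat)
    Path(genes_path).write_text("".join(g + "\n" for g in X.gene_names))
    Path(cells_path).write_text("".join(c + "\n" for c in X.cell_ids))


def write_gene_table(
    path: str | Path,
    records: Iterable[tuple],
    columns: Sequence[str],
) -> None:
    """Write (gene, value...) records as a TSV with header, order preserved."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    pd.DataFrame(records, columns=list(columns)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_cell_annotation(path: str | Path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("annotation needs two columns: cell_id, group")
    return CellAnnotation(
        [str(c) for c in df.iloc[:, 0]], list(df.iloc[:, 1])
    )


def write_cell_annotation(path: str | Path, ann: CellAnnotation) -> None:
    pd.DataFrame({"cell_id": ann.cell_ids, "group": ann.group}).to_csv(
        path, sep="\t", index=False
    )
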