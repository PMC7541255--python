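"""Reading and writing expression matrices and label files.

Supported formats: dense TSV/CSV (first row = cell ids, first column =
gene ids) and Matrix Market coordinate files with sibling ``genes.txt`` /
``barcodes.txt`` name files.  Matrices are always held genes x cells.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

VALID_UNITS = frozenset({"TPM", "CPM", "RPKM", "FPKM", "READS", "QN", "UNKNOWN"})


class ExpressionValidationError(ValueError):
    """Raised when an expression matrix violates its invariants."""


class ExpressionParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """A genes x cells nonnegative expression matrix with id metadata.

    Attributes
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Nonnegative, finite expression values.
    gene_ids : tuple of str
        Unique row identifiers.
    cell_ids : tuple of str
        Unique column identifiers.
    units : str
        One of TPM, CPM, RPKM, FPKM, READS, QN, UNKNOWN.  Metadata only.
    """

    values: np.ndarray
    gene_ids: tuple
    cell_ids: tuple
    units: str = "UNKNOWN"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if values.ndim != 2:
            raise ExpressionValidationError(f"expected 2-D matrix, got {values.ndim}-D")
        if self.units not in VALID_UNITS:
            raise ExpressionValidationError(
                f"unknown units {self.units!r}; expected one of {sorted(VALID_UNITS)}"
            )
        if len(self.gene_ids) != values.shape[0]:
            raise ExpressionValidationError(
                f"{len(self.gene_ids)} gene ids for {values.shape[0]} rows"
            )
        if len(self.cell_ids) != values.shape[1]:
            raise ExpressionValidationError(
                f"{len(self.cell_ids)} cell ids for {values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ExpressionValidationError("duplicate cell ids")
        if not np.all(np.isfinite(values)):
            raise ExpressionValidationError("non-finite expression values")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ExpressionValidationError(
                f"negative value {values[i, j]} at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other):
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and self.units == other.units
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )


def _names_paths(mtx_path: str):
    d = os.path.dirname(os.path.abspath(mtx_path))
    return os.path.join(d, "genes.txt"), os.path.join(d, "barcodes.txt")


def _read_names(path: str) -> list:
    if not os.path.exists(path):
        raise ExpressionParseError(f"missing sibling names file: {path}")
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def read_expression(
    path: str,
    format: str = "tsv",
    orientation: str = "genes_by_cells",
    units: str = "UNKNOWN",
) -> ExpressionMatrix:
    """Read an expression matrix into genes x cells orientation.

    Parameters
    ----------
    path : str
        Input file.  For ``mtx``, sibling ``genes.txt`` and ``barcodes.txt``
        files must sit next to the matrix file.
    format : {"tsv", "csv", "mtx"}
    orientation : {"genes_by_cells", "cells_by_genes"}
        Layout of the file on disk; the returned matrix is always
        genes x cells.
    units : str
        Units label to attach (metadata only).
    """
    if format not in ("tsv", "csv", "mtx"):
        raise ValueError(f"unsupported format {format!r}")
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unsupported orientation {orientation!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if format == "mtx":
        genes_path, cells_path = _names_paths(path)
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError with line info
            raise ExpressionParseError(f"malformed MTX file {path}: {exc}") from exc
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        row_ids = _read_names(genes_path)
        col_ids = _read_names(cells_path)
    else:
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(
                path, sep=sep, header=0, index_col=0, float_precision="round_trip"
            )
        except Exception as exc:
            raise ExpressionParseError(f"malformed {format} file {path}: {exc}") from exc
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            raise ExpressionParseError(
                f"non-numeric values in {path}, column(s) {list(bad)[:3]}"
            )
        values = df.to_numpy(dtype=np.float64)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]

    if orientation == "cells_by_genes":
        values = values.T
        row_ids, col_ids = col_ids, row_ids

    return ExpressionMatrix(values=values, gene_ids=row_ids, cell_ids=col_ids, units=units)


def write_expression(M: ExpressionMatrix, path: str, format: str = "tsv") -> None:
    """Write genes x cells; for ``mtx`` also writes genes.txt / barcodes.txt."""
    if format == "mtx":
        genes_path, cells_path = _names_paths(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(M.values))
        with open(genes_path, "w") as fh:
            fh.write("\n".join(M.gene_ids) + "\n")
        with open(cells_path, "w") as fh:
            fh.write("\n".join(M.cell_ids) + "\n")
        return
    if format not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = pd.DataFrame(M.values, index=list(M.gene_ids), columns=list(M.cell_ids))
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_labels(path: str) -> list:
    """Read a one-column label file (one label per cell, no header)."""
    with open(path) as fh:
        labels = [line.strip() for line in fh if line.strip() != ""]
    if not labels:
        raise ExpressionParseError(f"empty label file {path}")
    return labels


def write_labels(labels, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(x) for x in labels) + "\n")


def subsample_cells(M: ExpressionMatrix, max_cells: int, seed: int) -> ExpressionMatrix:
    """Return at most ``max_cells`` columns, chosen uniformly without
    replacement with column order preserved.  A no-op when n <= max_cells."""
    if max_cells < 2:
        raise ValueError("max_cells must be >= 2")
    if M.n_cells <= max_cells:
        return M
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(M.n_cells, size=max_cells, replace=False))
    return replace(
        M,
        values=M.values[:, keep],
        cell_ids=tuple(M.cell_ids[i] for i in keep),
    )
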