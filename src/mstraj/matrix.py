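"""Expression-matrix container and plain-text IO.

Matrices are genes x cells, dense float64.  Supported on-disk formats:

* Matrix Market (``.mtx``) with sidecar ``<stem>.genes.txt`` /
  ``<stem>.cells.txt`` name files (one identifier per line);
* delimited text (CSV/TSV): genes in rows, first column gene ids,
  header row of cell ids.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix"]

_LAYERS = ("counts", "lognorm")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with identifiers.

    Attributes
    ----------
    values
        2-D nonnegative array, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique string identifiers for rows / columns.
    layer
        ``"counts"`` (integer-valued) or ``"lognorm"``.
    cell_meta
        Optional per-cell metadata table indexed by cell id.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"
    cell_meta: pd.DataFrame | None = None
    strict: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if self.layer not in _LAYERS:
            raise ValueError(f"layer must be one of {_LAYERS}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if self.strict and self.layer == "counts":
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("layer='counts' requires integer-valued entries")
        if self.cell_meta is not None and len(self.cell_meta) != self.n_cells:
            raise ValueError("cell_meta row count must equal number of cells")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.values[idx], [self.gene_ids[i] for i in idx], list(self.cell_ids),
            layer=self.layer, cell_meta=self.cell_meta, strict=self.strict,
        )

    def subset_cells(self, cells) -> "ExpressionMatrix":
        idx = self.cell_index(cells)
        meta = self.cell_meta.iloc[idx] if self.cell_meta is not None else None
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.cell_ids[i] for i in idx],
            layer=self.layer, cell_meta=meta, strict=self.strict,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = path[:-4] if path.endswith(".mtx") else path
    return stem + ".genes.txt", stem + ".cells.txt"


def _read_names(path: str) -> list[str]:
    with io.open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("mtx", "csv", "tsv"):
        return ext
    raise ValueError(f"cannot infer matrix format from {path!r}; pass format=")


def read_matrix(path: str, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix; layer inferred (all-integer -> counts)."""
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        gpath, cpath = _sidecar_paths(path)
        genes, cells = _read_names(gpath), _read_names(cpath)
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"{len(genes)} gene names but {mat.shape[0]} matrix rows")
        if mat.shape[1] != len(cells):
            raise ValueError(
                f"{len(cells)} cell names but {mat.shape[1]} matrix columns")
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            mat = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric entries in {path}: {exc}") from exc
        genes, cells = [str(g) for g in df.index], [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    layer = "counts" if np.allclose(mat, np.round(mat)) else "lognorm"
    return ExpressionMatrix(mat, genes, cells, layer=layer)


def write_matrix(m: ExpressionMatrix, path: str, format: str | None = None) -> None:
    """Write a matrix; ``.mtx`` gets sidecar gene/cell name files."""
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values))
        gpath, cpath = _sidecar_paths(path)
        with io.open(gpath, "w", encoding="utf-8") as fh:
            fh.write("\n".join(m.gene_ids) + "\n")
        with io.open(cpath, "w", encoding="utf-8") as fh:
            fh.write("\n".join(m.cell_ids) + "\n")
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        m.to_frame().to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {fmt!r}")
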