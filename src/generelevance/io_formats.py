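"""Readers and writers for expression matrices, embeddings and result tables.

Supported on-disk formats are plain text: CSV/TSV with a header row and the
cell id in the first column, and MatrixMarket coordinate format for sparse
expression with sidecar newline-delimited gene and cell name files.  Floats
are written at full repr precision with "." as the decimal separator so
round trips are lossless to at least 8 significant digits.

Expression and embedding tables are matched by exact cell id string equality
*and order* by default — silent positional mismatches are the most dangerous
failure mode — with an optional reorder-by-name escape hatch.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .neighborhood import NeighborGraph, import_knn

#: above this many entries (cells × genes) a sparse matrix is never densified
#: wholesale; dense views are taken per neighborhood instead.
DENSIFY_LIMIT = 50_000_000

ORIENTATIONS = ("cells_by_genes", "genes_by_cells")


def _check_unique(ids, what: str) -> None:
    seen: dict = {}
    dups = []
    for name in ids:
        if name in seen:
            dups.append(name)
        seen[name] = True
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """cells×genes non-negative expression with cell and gene names.

    Library-size- and log-normalized expression is expected but not
    enforced.  ``values`` may be a dense ndarray or a scipy CSR matrix;
    row-wise dense views are available via :meth:`dense_rows`.
    """

    values: object  # (C, G) ndarray or csr_matrix
    cell_ids: list
    gene_ids: list

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
            data = self.values.data
        else:
            self.values = np.asarray(self.values, dtype=np.float64)
            if self.values.ndim != 2:
                raise ValueError("expression values must be a 2-D matrix")
            data = self.values
        if data.size and np.isnan(data).any():
            raise ValueError("expression matrix contains NaN entries")
        if data.size and (data < 0).any():
            raise ValueError("expression matrix contains negative values")
        C, G = self.values.shape
        if len(self.cell_ids) != C:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {C} rows")
        if len(self.gene_ids) != G:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {G} columns")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def dense_rows(self, rows) -> np.ndarray:
        """Dense (len(rows), G) float64 view of the requested cells."""
        if self.is_sparse:
            return np.asarray(self.values[list(rows)].todense(), dtype=np.float64)
        return self.values[list(rows)]

    def dense(self) -> np.ndarray:
        """Full dense matrix; refuses when C·G exceeds the densify limit."""
        if not self.is_sparse:
            return self.values
        if self.n_cells * self.n_genes > DENSIFY_LIMIT:
            raise MemoryError(
                f"refusing to densify a {self.n_cells}×{self.n_genes} sparse matrix "
                f"(limit {DENSIFY_LIMIT} entries); import a precomputed kNN graph instead"
            )
        return np.asarray(self.values.todense(), dtype=np.float64)


@dataclass
class Embedding:
    """cells×P embedding coordinates with named dimensions."""

    coords: np.ndarray
    dim_names: list
    cell_ids: list

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("embedding must be a 2-D cells×P matrix with P >= 1")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains NaN or infinite coordinates")
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.cell_ids, "cell ids")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("number of cell ids does not match embedding rows")
        self.dim_names = [str(d) for d in self.dim_names]
        if len(self.dim_names) != self.coords.shape[1]:
            raise ValueError("number of dimension names does not match embedding columns")

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def _sep_for(path, fmt: str | None) -> tuple:
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path!r}; pass format explicitly")
    if fmt not in ("csv", "tsv", "mtx"):
        raise ValueError(f"unknown format {fmt!r}")
    return fmt, ("," if fmt == "csv" else "\t")


def _read_names(path) -> list:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n")]


def read_expression(
    path,
    format: str | None = None,
    orientation: str = "cells_by_genes",
    genes_file=None,
    cells_file=None,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV (dense) or MTX (sparse).

    The result is always in cells×genes orientation regardless of the
    on-disk orientation.  For MTX, gene and cell names come from sidecar
    files (default ``<stem>.genes.txt`` / ``<stem>.cells.txt`` next to the
    matrix; gene/cell sidecars always list genes and cells respectively, and
    ``orientation`` declares which axis of the matrix is which).
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    fmt, sep = _sep_for(path, format)
    if fmt == "mtx":
        base = os.fspath(path)
        if base.endswith(".mtx"):
            base = base[: -len(".mtx")]
        genes_file = genes_file if genes_file is not None else base + ".genes.txt"
        cells_file = cells_file if cells_file is not None else base + ".cells.txt"
        mat = sp.csr_matrix(mmread(path))
        gene_ids = _read_names(genes_file)
        cell_ids = _read_names(cells_file)
        if orientation == "genes_by_cells":
            mat = mat.T.tocsr()
        if mat.shape[0] * mat.shape[1] <= DENSIFY_LIMIT:
            values: object = np.asarray(mat.todense(), dtype=np.float64)
        else:
            values = mat
        return ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)

    # pandas silently mangles duplicate header names; check the raw header
    raw_header = pd.read_csv(path, sep=sep, header=None, nrows=1).iloc[0].tolist()[1:]
    _check_unique([str(h) for h in raw_header],
                  "gene ids" if orientation == "cells_by_genes" else "cell ids")
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from None
    if orientation == "genes_by_cells":
        values = values.T
        gene_ids, cell_ids = list(df.index), list(df.columns)
    else:
        cell_ids, gene_ids = list(df.index), list(df.columns)
    return ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)


def read_embedding(path, format: str | None = None) -> Embedding:
    """Read a cells×P coordinate table (first column = cell id).

    Dimension names come from the header; non-numeric coordinate cells are
    reported with their row and column.
    """
    if format == "mtx":
        raise ValueError("embeddings must be dense CSV/TSV tables")
    fmt, sep = _sep_for(path, format if format else None)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"embedding table {path} has no coordinate columns")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric coordinate in {path}: column {col!r}, rows {list(bad[:5])}"
            )
        if coerced.isna().any():
            rows = list(df.index[coerced.isna()][:5])
            raise ValueError(f"missing coordinate in {path}: column {col!r}, rows {rows}")
    dim_names = [str(c) for c in df.columns]
    return Embedding(coords=df.to_numpy(dtype=np.float64), dim_names=dim_names,
                     cell_ids=list(df.index))


def pair(expr: ExpressionMatrix, emb: Embedding, reorder: bool = False):
    """Validate that expression and embedding describe the same cells.

    By default cell ids must be identical in content *and order*; with
    ``reorder=True`` the embedding is reordered to match the expression by
    name.  Returns the (possibly reordered) embedding.
    """
    if list(expr.cell_ids) == list(emb.cell_ids):
        return emb
    if not reorder:
        raise ValueError(
            "expression and embedding cell ids differ in content or order "
            "(pass reorder=True / --reorder to match by name)"
        )
    pos = {c: i for i, c in enumerate(emb.cell_ids)}
    missing = [c for c in expr.cell_ids if c not in pos]
    if missing or len(emb.cell_ids) != len(expr.cell_ids):
        raise ValueError(f"embedding is missing cells {missing[:5]} or has extras")
    order = [pos[c] for c in expr.cell_ids]
    return Embedding(coords=emb.coords[order], dim_names=emb.dim_names,
                     cell_ids=list(expr.cell_ids))


def write_expression(expr: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write an expression matrix as CSV/TSV (dense) or MTX + sidecars."""
    fmt, sep = _sep_for(path, format)
    if fmt == "mtx":
        from scipy.io import mmwrite

        base = os.fspath(path)
        if base.endswith(".mtx"):
            base = base[: -len(".mtx")]
        mat = expr.values if expr.is_sparse else sp.csr_matrix(expr.values)
        mmwrite(os.fspath(path), mat)
        for fname, names in ((base + ".genes.txt", expr.gene_ids),
                             (base + ".cells.txt", expr.cell_ids)):
            with open(fname, "w") as fh:
                fh.write("\n".join(names) + ("\n" if names else ""))
        return
    df = pd.DataFrame(np.asarray(expr.dense()), index=expr.cell_ids, columns=expr.gene_ids)
    df.index.name = "cell_id"
    df.to_csv(path, sep=sep)


def write_embedding(emb: Embedding, path, format: str | None = None) -> None:
    fmt, sep = _sep_for(path, format)
    if fmt == "mtx":
        raise ValueError("embeddings are written as dense CSV/TSV tables")
    df = pd.DataFrame(emb.coords, index=emb.cell_ids, columns=emb.dim_names)
    df.index.name = "cell_id"
    df.to_csv(path, sep=sep)


def read_knn_tsv(path) -> NeighborGraph:
    """Read a headerless TSV of k neighbor indices per row (0-based,
    row order = cell order)."""
    idx = pd.read_csv(path, sep="\t", header=None).to_numpy()
    return import_knn(idx)


def write_knn_tsv(graph: NeighborGraph, path) -> None:
    pd.DataFrame(graph.neighbor_index).to_csv(path, sep="\t", header=False, index=False)


def write_relevance_tables(result, out_dir) -> dict:
    """Write the global ranking, binned local relevance and map tables.

    Returns a manifest mapping table names to written paths.  Ordering is
    deterministic: descending relevance with lexicographic gene tie-break.
    Empty gene sets produce header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}

    path = out_dir / "global_relevance.tsv"
    result.global_ranking.to_csv(path, sep="\t", index=False,
                                 columns=["gene", "global_relevance", "rank"])
    manifest["global_relevance"] = path

    path = out_dir / "local_relevance_bins.tsv"
    result.local_relevance_bins.to_csv(path, sep="\t", index=False)
    manifest["local_relevance_bins"] = path

    if result.map_labels is not None:
        path = out_dir / "relevance_map.tsv"
        result.map_labels.to_csv(path, sep="\t", index=False)
        manifest["relevance_map"] = path
    return manifest
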