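"""k-nearest-neighbor graphs in gene expression space.

Gene relevance estimates expression gradients from each cell's neighborhood
in *expression* space (not embedding space), so the graph is built on the
cells×genes matrix under one of three distances: euclidean, cosine, or
spearman rank-correlation distance (the default, and the most robust choice
for zero-inflated single-cell data since it only depends on within-cell
expression ranks).

If a kNN search was already performed while constructing the embedding, the
resulting index matrix can be imported directly via :func:`import_knn`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

logger = logging.getLogger("generelevance")

VALID_METRICS = ("euclidean", "cosine", "spearman")

#: row-chunk size for pairwise distance computation; bounds memory at
#: chunk_size × n_cells floats per chunk.
DEFAULT_CHUNK_SIZE = 1024


def default_k(n_cells: int) -> int:
    """Default neighborhood size: ``min(C-1, max(10, round(sqrt(C))))``.

    The sqrt(C) scaling keeps neighborhoods local as the dataset grows while
    the floor of 10 keeps the median finite difference stable for small C.
    """
    return min(n_cells - 1, max(10, round(math.sqrt(n_cells))))


@dataclass
class NeighborGraph:
    """Directed kNN graph: row c lists the k nearest cells to cell c.

    Invariants: no self-neighbors, k distinct in-range indices per row,
    k < number of cells.
    """

    k: int
    neighbor_index: np.ndarray  # (C, k) int
    distance_metric: str | None = None
    source: str = "computed"  # {"computed", "imported"}

    def __post_init__(self) -> None:
        idx = np.asarray(self.neighbor_index)
        if idx.ndim != 2:
            raise ValueError("neighbor_index must be a 2-D cells×k matrix")
        if not np.issubdtype(idx.dtype, np.integer):
            if not np.all(idx == np.floor(idx)):
                raise ValueError("neighbor_index must contain integers")
            idx = idx.astype(np.int64)
        self.neighbor_index = idx
        n_cells, k = idx.shape
        if k != self.k:
            raise ValueError(f"k={self.k} but neighbor_index has {k} columns")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k >= n_cells:
            raise ValueError(f"k={self.k} must be smaller than the number of cells ({n_cells})")
        bad_range = np.where((idx < 0) | (idx >= n_cells))[0]
        if bad_range.size:
            rows = sorted(set(bad_range.tolist()))
            raise ValueError(f"neighbor indices out of range [0, {n_cells}) in rows {rows}")
        self_rows = np.where((idx == np.arange(n_cells)[:, None]).any(axis=1))[0]
        if self_rows.size:
            raise ValueError(f"cells listed as their own neighbor in rows {self_rows.tolist()}")
        dup_rows = [c for c in range(n_cells) if np.unique(idx[c]).size != k]
        if dup_rows:
            raise ValueError(f"duplicate neighbors within rows {dup_rows}")

    @property
    def n_cells(self) -> int:
        return self.neighbor_index.shape[0]


def _spearman_parts(X: np.ndarray, cell_ids) -> tuple[np.ndarray, np.ndarray]:
    """Centered average-rank rows and their sums of squares.

    Ranks are half-integers and their mean is exactly (G+1)/2, so the
    centered values, squares and dot products below are all exact multiples
    of 1/4 in float64 — distance ties are therefore reproducible.
    """
    const = np.where(np.ptp(X, axis=1) == 0)[0]
    if const.size:
        names = [cell_ids[i] for i in const[:10]]
        raise ValueError(
            "spearman distance undefined for cells with constant expression "
            f"vectors: {names}"
        )
    R = rankdata(X, axis=1)  # average ranks for ties
    Rc = R - (X.shape[1] + 1) / 2.0
    ss = np.einsum("ij,ij->i", Rc, Rc)
    return Rc, ss


def _cosine_check(X: np.ndarray, cell_ids) -> None:
    zero = np.where(~np.any(X != 0, axis=1))[0]
    if zero.size:
        names = [cell_ids[i] for i in zero[:10]]
        raise ValueError(f"cosine distance undefined for all-zero cells: {names}")


def build_knn(
    expr,
    k: int | None = None,
    metric: str = "spearman",
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> NeighborGraph:
    """Find each cell's k nearest neighbors in expression space.

    Ties at the k-th neighbor are broken by ascending cell index (stable
    argsort over the explicit distance rows), so results are deterministic
    across platforms and chunk sizes.

    Parameters
    ----------
    expr : ExpressionMatrix
    k : int, optional
        Neighborhood size; defaults to :func:`default_k`.
    metric : {"euclidean", "cosine", "spearman"}
    """
    if metric not in VALID_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {VALID_METRICS}")
    X = expr.dense()
    n_cells = X.shape[0]
    if k is None:
        k = default_k(n_cells)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n_cells:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n_cells})")

    if metric == "spearman":
        Rc, ss = _spearman_parts(X, expr.cell_ids)
    elif metric == "cosine":
        _cosine_check(X, expr.cell_ids)

    neighbor_index = np.empty((n_cells, k), dtype=np.int64)
    for start in range(0, n_cells, chunk_size):
        stop = min(start + chunk_size, n_cells)
        if metric == "spearman":
            num = Rc[start:stop] @ Rc.T
            D = 1.0 - num / np.sqrt(np.outer(ss[start:stop], ss))
        else:
            D = cdist(X[start:stop], X, metric=metric)
        D[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.argsort(D, axis=1, kind="stable")
        neighbor_index[start:stop] = order[:, :k]
    return NeighborGraph(k=k, neighbor_index=neighbor_index, distance_metric=metric, source="computed")


def import_knn(neighbor_index: np.ndarray, distance_metric: str | None = None) -> NeighborGraph:
    """Wrap a precomputed neighbor index matrix (e.g. from the embedding step).

    The matrix must satisfy all :class:`NeighborGraph` invariants; no
    distances are recomputed.
    """
    idx = np.asarray(neighbor_index)
    if idx.ndim != 2:
        raise ValueError("neighbor_index must be a 2-D cells×k matrix")
    graph = NeighborGraph(
        k=idx.shape[1], neighbor_index=idx, distance_metric=distance_metric, source="imported"
    )
    return graph
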