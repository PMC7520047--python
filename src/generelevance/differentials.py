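"""Finite-difference estimates of per-cell expression gradients.

The differential d_gc of gene g at cell c approximates the partial
derivatives of expression x_gc with respect to each embedding coordinate
s_pc.  It is estimated per dimension p as the median finite-difference
quotient over the cell's expression-space neighborhood::

    (d_gc)_p = median_{n in NN_k(c)} (x_gc - x_gn) / (s_pn - s_pc)

with a dropout rule: if x_gc = 0 the differential is undefined (NA), since a
technical zero carries no gradient information.  Note the quotient as
defined above equals the *negative* of the forward-difference slope; this is
irrelevant for relevance scores (which use the norm), and the exported
expression-change field can be negated via ``orient_forward``.

Neighbors with s_pn = s_pc are excluded from dimension p's median (the
quotient is undefined); if every neighbor is excluded for some dimension the
whole differential is marked missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neighborhood import NeighborGraph

logger = logging.getLogger("generelevance")


@dataclass
class DifferentialTensor:
    """cells×genes×P tensor of median finite differences with missingness.

    ``values[c, g]`` is all-NaN exactly where ``missing_mask[c, g]`` is True:
    either x_gc = 0 (dropout) or some dimension had no valid quotient.
    """

    values: np.ndarray  # (C, G, P), NaN where missing
    missing_mask: np.ndarray  # (C, G) bool
    cell_ids: list
    gene_ids: list
    dim_names: list
    graph: NeighborGraph | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_dims(self) -> int:
        return self.values.shape[2]


def estimate_differentials(
    expr,
    emb,
    graph: NeighborGraph,
    drop_zero_neighbors: bool = False,
) -> DifferentialTensor:
    """Estimate the differential tensor over all cells and genes.

    Parameters
    ----------
    expr : ExpressionMatrix
    emb : Embedding
        Must share cell order with ``expr``.
    graph : NeighborGraph
        Neighborhoods in expression space.
    drop_zero_neighbors : bool
        If True, neighbors with x_gn = 0 are also excluded from gene g's
        medians (stricter than the default rule, which only treats the
        center cell's zero as missing).

    Complexity O(C·G·P·k), computed one cell at a time so at most
    k·G·P floats are materialized per step.
    """
    n_cells, n_genes = expr.shape
    if emb.coords.shape[0] != n_cells:
        raise ValueError(
            f"expression has {n_cells} cells but embedding has {emb.coords.shape[0]}"
        )
    if graph.n_cells != n_cells:
        raise ValueError(
            f"expression has {n_cells} cells but neighbor graph has {graph.n_cells}"
        )
    if list(expr.cell_ids) != list(emb.cell_ids):
        raise ValueError("expression and embedding cell ids differ in content or order")

    S = emb.coords
    n_dims = S.shape[1]
    values = np.empty((n_cells, n_genes, n_dims), dtype=np.float64)
    missing = np.zeros((n_cells, n_genes), dtype=bool)
    idx = graph.neighbor_index

    for c in range(n_cells):
        xc = expr.dense_rows([c])[0]  # (G,)
        nbrs = idx[c]
        xn = expr.dense_rows(nbrs)  # (k, G)
        den = S[nbrs] - S[c]  # (k, P)
        den = np.where(den == 0.0, np.nan, den)
        quot = (xc[None, :, None] - xn[:, :, None]) / den[:, None, :]  # (k, G, P)
        if drop_zero_neighbors:
            quot[xn == 0.0] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            med = np.nanmedian(quot, axis=0)  # (G, P)
        bad = np.isnan(med).any(axis=1) | (xc == 0.0)
        med[bad] = np.nan
        values[c] = med
        missing[c] = bad

    all_missing = missing.all(axis=0)
    if all_missing.any():
        names = [expr.gene_ids[g] for g in np.where(all_missing)[0][:20]]
        logger.info("%d gene(s) have no defined differential in any cell: %s",
                    int(all_missing.sum()), names)
    logger.info("differential NA fraction: %.4f", float(missing.mean()))

    return DifferentialTensor(
        values=values,
        missing_mask=missing,
        cell_ids=list(expr.cell_ids),
        gene_ids=list(expr.gene_ids),
        dim_names=list(emb.dim_names),
        graph=graph,
    )


def expression_change_field(
    diff: DifferentialTensor, gene: str, orient_forward: bool = False
) -> pd.DataFrame:
    """Per-cell expression-change vectors for one gene, for arrow overlays.

    Returns a DataFrame indexed by cell id with one column per embedding
    dimension plus a boolean ``missing`` column; cell order matches the
    embedding.  With ``orient_forward`` the field is negated so arrows point
    in the direction of increasing expression.
    """
    try:
        g = diff.gene_ids.index(gene)
    except ValueError:
        raise KeyError(f"unknown gene {gene!r}") from None
    field = diff.values[:, g, :]
    if orient_forward:
        field = -field
    out = pd.DataFrame(field, index=pd.Index(diff.cell_ids, name="cell_id"),
                       columns=diff.dim_names)
    out["missing"] = diff.missing_mask[:, g]
    return out
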