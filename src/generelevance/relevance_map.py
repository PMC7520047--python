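"""Gene relevance maps: per-cell most relevant gene with label smoothing.

For a gene pool Ω (typically the globally most relevant genes), each cell is
initially labeled with its highest-scoring gene from Ω.  Each smoothing step
then replaces, for every cell, the per-gene value with the fraction of its k
out-neighbors currently carrying that gene as label, and takes the argmax —
a synchronous neighbor-majority vote on the directed kNN graph.  Smoothing
removes single-cell speckle; more steps (larger m) erase genes relevant only
in small regions, so m acts as a locality/sensitivity parameter.

Tie rule everywhere: the lexicographically smallest gene id wins.  Cells
where every pool gene is undefined start unlabeled; an unlabeled cell picks
up a label as soon as it has at least one labeled neighbor, and a labeled
cell with no labeled neighbors keeps its label with support 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .neighborhood import NeighborGraph
from .relevance import RelevanceResult, ScoreMatrix

#: sentinel label for cells whose candidate set is empty
UNLABELED = None

DEFAULT_SMOOTHING_STEPS = 1


@dataclass
class MapState:
    """Per-cell labels l_c^m after m smoothing steps.

    ``support`` is the fraction of neighbors agreeing with the label at the
    final smoothing step (NaN at m=0, where no graph has been consulted).
    """

    labels: np.ndarray  # (C,) object: gene id or None
    m: int
    gene_pool: list
    support: np.ndarray  # (C,) float
    cell_ids: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "most_relevant_gene": [l if l is not None else "" for l in self.labels],
                "support": self.support,
                "m": self.m,
            }
        )


def initial_labels(scores: ScoreMatrix, gene_pool: Sequence[str]) -> MapState:
    """Label each cell with its highest-scoring pool gene (m = 0).

    Cells where every pool gene has a missing score are left unlabeled.
    """
    pool = list(gene_pool)
    if not pool:
        raise ValueError("gene pool Ω must be nonempty")
    if len(set(pool)) != len(pool):
        raise ValueError("gene pool Ω contains duplicates")
    unknown = sorted(set(pool) - set(scores.gene_ids))
    if unknown:
        raise KeyError(f"unknown genes in Ω: {unknown}")

    # lexicographic column order makes np.argmax's first-max rule the tie rule
    pool_sorted = sorted(pool)
    cols = [scores.gene_ids.index(g) for g in pool_sorted]
    sub = scores.scores[:, cols]
    filled = np.where(np.isnan(sub), -np.inf, sub)
    any_defined = ~np.all(np.isnan(sub), axis=1)
    best = np.argmax(filled, axis=1)

    labels = np.empty(scores.n_cells, dtype=object)
    labels[:] = UNLABELED
    labels[any_defined] = np.array(pool_sorted, dtype=object)[best[any_defined]]
    support = np.full(scores.n_cells, np.nan)
    return MapState(labels=labels, m=0, gene_pool=pool, support=support,
                    cell_ids=list(scores.cell_ids))


def smooth(state: MapState, graph: NeighborGraph, steps: int = 1) -> MapState:
    """Apply ``steps`` rounds of synchronous neighbor-majority smoothing.

    Each round uses the labels of the previous round only (the recursion
    depends purely on l^{m-1}).  Unlabeled neighbors vote for no gene.
    ``steps=0`` returns an identical copy.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    n_cells = len(state.labels)
    if graph.n_cells != n_cells:
        raise ValueError("neighbor graph and map state disagree on the number of cells")

    pool_sorted = sorted(state.gene_pool)
    code_of = {g: i for i, g in enumerate(pool_sorted)}
    codes = np.array([code_of[l] if l is not None else -1 for l in state.labels], dtype=np.int64)
    support = state.support.copy()
    idx = graph.neighbor_index
    k = graph.k

    for _ in range(steps):
        nbr_codes = codes[idx]  # (C, k)
        counts = np.zeros((n_cells, len(pool_sorted)), dtype=np.int64)
        rows = np.repeat(np.arange(n_cells), k)
        flat = nbr_codes.ravel()
        labeled = flat >= 0
        np.add.at(counts, (rows[labeled], flat[labeled]), 1)
        total = counts.sum(axis=1)
        best = np.argmax(counts, axis=1)  # first max = lexicographically smallest
        new_codes = codes.copy()
        has_vote = total > 0
        new_codes[has_vote] = best[has_vote]
        support = np.where(has_vote, counts[np.arange(n_cells), best] / k, 0.0)
        support[codes == -1] = np.where(has_vote[codes == -1], support[codes == -1], np.nan)
        codes = new_codes

    labels = np.empty(n_cells, dtype=object)
    labels[:] = UNLABELED
    for i, c in enumerate(codes):
        if c >= 0:
            labels[i] = pool_sorted[c]
    return MapState(labels=labels, m=state.m + steps, gene_pool=list(state.gene_pool),
                    support=support, cell_ids=list(state.cell_ids))


def select_gene_pool(
    result: RelevanceResult,
    rank_cutoff: int | None = None,
    top_n: int | None = None,
    genes: Sequence[str] | None = None,
) -> list:
    """Choose the gene pool Ω for a relevance map.

    An explicit ``genes`` list bypasses global relevance entirely.
    Otherwise the top ``top_n`` genes of the deterministic global ranking
    are taken; if ``top_n`` is absent, the rank cutoff (rgmax) itself is
    used as the pool size, making rgmax the map's sensitivity parameter.
    """
    if genes is not None:
        genes = list(genes)
        if not genes:
            raise ValueError("explicit gene pool must be nonempty")
        return genes
    size = top_n if top_n is not None else (
        rank_cutoff if rank_cutoff is not None else result.rank_cutoff
    )
    if size < 1:
        raise ValueError("gene pool size must be >= 1")
    return list(result.global_ranking["gene"].head(size))


def build_map(
    scores: ScoreMatrix,
    graph: NeighborGraph,
    gene_pool: Sequence[str],
    m: int = DEFAULT_SMOOTHING_STEPS,
) -> MapState:
    """Convenience: initial labels followed by m smoothing steps."""
    state = initial_labels(scores, gene_pool)
    if m > 0:
        state = smooth(state, graph, m)
    return state
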