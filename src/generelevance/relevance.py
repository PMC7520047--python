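"""Per-cell gene relevance scores, rankings, and local/global relevance.

The relevance score of gene g in cell c is the euclidean norm ||d_gc||_2 of
its differential: the magnitude of expression change per unit displacement
in the embedding at that cell.  Within each cell, genes are ranked by score
(rank 1 = largest).  For a cell set Ψ and rank cutoff rgmax, the local gene
relevance is the fraction of cells in Ψ where the gene ranks above the
cutoff::

    LR(g, Ψ) = #{c in Ψ : rank_c(g) < rgmax} / |Ψ|

(strict inequality, so rgmax = 10 counts ranks 1–9; an inclusive variant is
available).  Global relevance is LR over the set of all cells.  Binned local
relevance evaluates LR over the cells falling into each tile of an
equal-width grid on the first two embedding dimensions, yielding the data
behind local-relevance plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, rankdata

DEFAULT_RANK_CUTOFF = 10
DEFAULT_BINS = 16


@dataclass
class ScoreMatrix:
    """cells×genes relevance scores ||d_gc||_2; NaN where undefined."""

    scores: np.ndarray  # (C, G), NaN = missing
    cell_ids: list
    gene_ids: list

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]

    @property
    def n_genes(self) -> int:
        return self.scores.shape[1]


@dataclass
class RankMatrix:
    """Per-cell competition (min) ranks of the scores, descending.

    ``ranks[c, g]`` is 1 for the highest-scoring gene of cell c; genes with
    missing scores have NaN ranks and the remaining genes are ranked
    compactly among the defined ones.  Ties share the better (smaller) rank.
    """

    ranks: np.ndarray  # (C, G) float, NaN = missing
    cell_ids: list
    gene_ids: list

    @property
    def n_cells(self) -> int:
        return self.ranks.shape[0]


@dataclass
class BinGrid:
    """Equal-width bin assignment of cells on the first two embedding axes.

    For 1-D embeddings ``n_bins_y`` is 1 and ``bin_y`` is all zeros.  The
    final interval on each axis is right-closed so cells at the coordinate
    maximum fall into the last bin.
    """

    n_bins_x: int
    n_bins_y: int
    edges_x: np.ndarray
    edges_y: np.ndarray | None
    bin_x: np.ndarray  # (C,) int
    bin_y: np.ndarray  # (C,) int


@dataclass
class RelevanceResult:
    """Bundle of the method's outputs plus full parameter provenance."""

    global_relevance: pd.Series  # index = gene id, values in [0, 1]
    global_ranking: pd.DataFrame  # columns: gene, global_relevance, rank
    local_relevance_bins: pd.DataFrame  # bin_x, bin_y, n_cells, gene, local_relevance
    rank_cutoff: int
    map_labels: pd.DataFrame | None = None  # cell_id, most_relevant_gene, support, m
    parameters: dict = field(default_factory=dict)


def compute_scores(diff) -> ScoreMatrix:
    """Euclidean norm of the differential over embedding dimensions (Eq. of
    the score); missing differentials propagate to missing scores."""
    v = diff.values
    scores = np.sqrt((v * v).sum(axis=2))
    return ScoreMatrix(scores=scores, cell_ids=list(diff.cell_ids), gene_ids=list(diff.gene_ids))


def rank_genes_per_cell(scores: ScoreMatrix) -> RankMatrix:
    """Rank genes within each cell from most to least relevant."""
    s = scores.scores
    ranks = np.full_like(s, np.nan)
    for c in range(s.shape[0]):
        defined = ~np.isnan(s[c])
        if defined.any():
            ranks[c, defined] = rankdata(-s[c, defined], method="min")
    return RankMatrix(ranks=ranks, cell_ids=list(scores.cell_ids), gene_ids=list(scores.gene_ids))


def _relevant_mask(ranks: np.ndarray, rank_cutoff: int, inclusive: bool) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if inclusive:
            return ranks <= rank_cutoff
        return ranks < rank_cutoff


def local_relevance(
    ranks: RankMatrix,
    cell_set: Iterable[int],
    rank_cutoff: int = DEFAULT_RANK_CUTOFF,
    inclusive: bool = False,
) -> pd.Series:
    """Local gene relevance LR(g, Ψ) for a nonempty set of cell indices Ψ.

    Missing ranks never count as relevant.  NaN comparisons are False, so a
    gene undefined in some cells of Ψ is simply not counted there.
    """
    cells = np.asarray(list(cell_set), dtype=np.int64)
    if cells.size == 0:
        raise ValueError("cell set Ψ must be nonempty")
    if rank_cutoff < 1:
        raise ValueError("rank cutoff must be >= 1")
    hits = _relevant_mask(ranks.ranks[cells], rank_cutoff, inclusive)
    lr = hits.sum(axis=0) / cells.size
    return pd.Series(lr, index=pd.Index(ranks.gene_ids, name="gene"), name="local_relevance")


def global_relevance(
    ranks: RankMatrix,
    rank_cutoff: int = DEFAULT_RANK_CUTOFF,
    inclusive: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Global gene relevance: LR over the set of all cells, plus a ranking.

    Returns ``(gr, ranking)`` where ``ranking`` orders genes by descending
    relevance, ties broken lexicographically by gene id, with rank numbers
    1..G.
    """
    gr = local_relevance(ranks, range(ranks.n_cells), rank_cutoff, inclusive)
    gr = gr.rename("global_relevance")
    ranking = gr.reset_index()
    ranking = ranking.sort_values(
        ["global_relevance", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return gr, ranking


def bin_embedding(emb, n_bins_x: int = DEFAULT_BINS, n_bins_y: int = DEFAULT_BINS) -> BinGrid:
    """Evenly divide the first two embedding dimensions into a bin grid.

    For 1-D embeddings a 1-D bin vector is produced.  Degenerate axes (all
    coordinates equal) collapse every cell into the first bin.
    """
    if n_bins_x < 1 or n_bins_y < 1:
        raise ValueError("number of bins must be >= 1")
    coords = emb.coords

    def _assign(x: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = float(x.min()), float(x.max())
        span = hi - lo
        if span == 0.0:
            edges = np.linspace(lo, lo + 1.0, n + 1)
            return edges, np.zeros(x.shape[0], dtype=np.int64)
        w = span / n
        ix = np.floor((x - lo) / w).astype(np.int64)
        np.clip(ix, 0, n - 1, out=ix)
        return np.linspace(lo, hi, n + 1), ix

    edges_x, bx = _assign(coords[:, 0], n_bins_x)
    if coords.shape[1] >= 2:
        edges_y, by = _assign(coords[:, 1], n_bins_y)
    else:
        n_bins_y = 1
        edges_y, by = None, np.zeros(coords.shape[0], dtype=np.int64)
    return BinGrid(n_bins_x=n_bins_x, n_bins_y=n_bins_y, edges_x=edges_x,
                   edges_y=edges_y, bin_x=bx, bin_y=by)


def binned_local_relevance(
    ranks: RankMatrix,
    grid: BinGrid,
    rank_cutoff: int = DEFAULT_RANK_CUTOFF,
    genes: Sequence[str] | None = None,
    inclusive: bool = False,
) -> pd.DataFrame:
    """LR(g, Ψ_b) for the cells falling into each bin of the grid.

    Empty bins are reported with ``n_cells`` 0 and NaN relevance (undefined,
    not zero).  Cell counts are included so plots can fade low-count bins.
    Rows are ordered by bin, then descending relevance with lexicographic
    gene tie-break.
    """
    if grid.bin_x.shape[0] != ranks.n_cells:
        raise ValueError("bin grid and rank matrix disagree on the number of cells")
    gene_ids = list(ranks.gene_ids)
    if genes is not None:
        unknown = sorted(set(genes) - set(gene_ids))
        if unknown:
            raise KeyError(f"unknown genes {unknown}")
        cols = [gene_ids.index(g) for g in genes]
        gene_names = list(genes)
    else:
        cols = list(range(len(gene_ids)))
        gene_names = gene_ids

    hits = _relevant_mask(ranks.ranks[:, cols], rank_cutoff, inclusive)
    flat = grid.bin_x * grid.n_bins_y + grid.bin_y
    n_bins = grid.n_bins_x * grid.n_bins_y
    counts = np.bincount(flat, minlength=n_bins)
    hit_sums = np.zeros((n_bins, len(cols)))
    np.add.at(hit_sums, flat, hits.astype(np.float64))

    records = []
    for b in range(n_bins):
        bx, by = divmod(b, grid.n_bins_y)
        n = int(counts[b])
        lr = hit_sums[b] / n if n > 0 else np.full(len(cols), np.nan)
        for j, g in enumerate(gene_names):
            records.append((bx, by, n, g, lr[j]))
    out = pd.DataFrame(records, columns=["bin_x", "bin_y", "n_cells", "gene", "local_relevance"])
    out = out.sort_values(
        ["bin_x", "bin_y", "local_relevance", "gene"],
        ascending=[True, True, False, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    return out


def cutoff_stability(
    ranks: RankMatrix,
    cutoffs: Sequence[int] = (10, 50, 100),
    top_n: int = 5,
    inclusive: bool = False,
) -> dict:
    """Robustness of the global ranking to the rank cutoff rgmax.

    Computes the global ranking at each cutoff, Kendall-tau correlations of
    the relevance values between consecutive cutoffs, and the top-``top_n``
    gene sets.  The method's claim is that the most relevant genes are
    stable even for large cutoffs.
    """
    rankings = {}
    values = {}
    for rc in cutoffs:
        gr, ranking = global_relevance(ranks, rank_cutoff=rc, inclusive=inclusive)
        rankings[rc] = ranking
        values[rc] = gr
    taus = {}
    cuts = list(cutoffs)
    for a, b in zip(cuts[:-1], cuts[1:]):
        tau = kendalltau(values[a].to_numpy(), values[b].to_numpy()).statistic
        taus[(a, b)] = float(tau)
    top_sets = {rc: set(rankings[rc]["gene"].head(top_n)) for rc in cutoffs}
    return {"rankings": rankings, "kendall_tau": taus, "top_sets": top_sets}
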