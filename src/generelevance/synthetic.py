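"""Synthetic expression matrices with planted relevance structure.

The generator emulates the regime the method targets: non-negative,
zero-inflated (dropout) expression on a log-like continuous scale, over a
low-dimensional manifold.  Cells are placed on a simple embedding (a line,
a Y-shaped bifurcating layout, or a lattice); "planted" genes vary smoothly
(linearly or sigmoidally) with position along the manifold, within the whole
embedding or a sub-region such as one branch; all other genes are pure noise
around a constant baseline.  Dropout then zeroes entries independently.

All randomness derives from a single seed expanded into per-component
substreams, so outputs are bit-identical across runs and partial
regeneration (e.g. a new noise draw with the same embedding) is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EMBEDDING_KINDS = ("line", "two_branches", "grid")
EFFECTS = ("linear", "sigmoid")

# substream tags
_EMBED, _NOISE, _DROPOUT, _COUNTS = 1, 2, 3, 4


@dataclass(frozen=True)
class PlantedGene:
    """One gene whose expression follows the embedding within a region.

    ``region`` is "all", "trunk", "branch_a", "branch_b", or a tuple
    ("interval", lo, hi) on the pseudotime axis.  ``effect`` maps the
    relative position t in [0, 1] within the region to slope·t (linear) or
    a sigmoidal ramp of the same amplitude.
    """

    gene_index: int
    region: object = "all"
    effect: str = "linear"
    slope: float = 2.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic benchmark.

    Defaults model a few hundred cells over a bifurcating trajectory with a
    handful of strongly varying marker genes among mostly-noise genes, on a
    log-normalized scale: baseline expression 1.0, gene-level noise sd 0.3,
    planted amplitude 2.0 (log units across the trajectory), 20% dropout.
    """

    n_cells: int = 300
    n_genes: int = 200
    embedding_kind: str = "two_branches"
    planted_genes: tuple = ()
    dropout_rate: float = 0.2
    noise_sd: float = 0.3
    baseline: float = 1.0
    branch_point: float = 0.5
    counts_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_kind not in EMBEDDING_KINDS:
            raise ValueError(f"unknown embedding kind {self.embedding_kind!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cells < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 cells and 1 gene")
        for pg in self.planted_genes:
            if not (0 <= pg.gene_index < self.n_genes):
                raise ValueError(f"planted gene index {pg.gene_index} out of range")
            if pg.effect not in EFFECTS:
                raise ValueError(f"unknown effect {pg.effect!r}")
            if pg.region in ("trunk", "branch_a", "branch_b") and self.embedding_kind != "two_branches":
                raise ValueError(
                    f"region {pg.region!r} requires the two_branches embedding"
                )
        idx = [pg.gene_index for pg in self.planted_genes]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate planted gene indices")

    @classmethod
    def benchmark(cls, seed: int = 0) -> "SyntheticSpec":
        """The default benchmark: 5 planted genes across the full embedding
        (3 linear, 2 sigmoidal), 195 pure-noise genes."""
        planted = tuple(
            PlantedGene(i, "all", "linear" if i < 3 else "sigmoid", 2.0) for i in range(5)
        )
        return cls(planted_genes=planted, seed=seed)

    @classmethod
    def branch_benchmark(cls, seed: int = 0) -> "SyntheticSpec":
        """Like :meth:`benchmark` but the fifth planted gene is restricted
        to branch A, for local-recovery tests."""
        planted = tuple(
            PlantedGene(i, "all", "linear" if i < 3 else "sigmoid", 2.0) for i in range(4)
        ) + (PlantedGene(4, "branch_a", "linear", 2.0),)
        return cls(planted_genes=planted, seed=seed)


def _embedding(spec: SyntheticSpec):
    """Pseudotime t, branch assignment, and coordinates for each cell."""
    rng = np.random.default_rng([spec.seed, _EMBED])
    C = spec.n_cells
    if spec.embedding_kind == "line":
        t = np.sort(rng.uniform(0.0, 1.0, C))
        coords = t[:, None]
        branch = np.zeros(C, dtype=np.int64)
    elif spec.embedding_kind == "two_branches":
        t = rng.uniform(0.0, 1.0, C)
        branch = rng.integers(0, 2, C)
        bp = spec.branch_point
        y = np.where(t < bp, 0.0, (t - bp) * np.where(branch == 0, 1.0, -1.0))
        coords = np.column_stack([t, y])
    else:  # grid
        nx = int(np.ceil(np.sqrt(C)))
        xs, ys = np.meshgrid(np.arange(nx), np.arange(nx), indexing="ij")
        pts = np.column_stack([xs.ravel(), ys.ravel()])[:C].astype(np.float64)
        coords = pts / max(nx - 1, 1)
        t = coords[:, 0].copy()
        branch = np.zeros(C, dtype=np.int64)
    return t, branch, coords


def _region_mask(spec: SyntheticSpec, region, t: np.ndarray, branch: np.ndarray):
    """Boolean membership and relative position t_rel in [0, 1]."""
    bp = spec.branch_point
    if region == "all":
        mask = np.ones(t.shape[0], dtype=bool)
        lo, hi = 0.0, 1.0
    elif region == "trunk":
        mask = t < bp
        lo, hi = 0.0, bp
    elif region in ("branch_a", "branch_b"):
        which = 0 if region == "branch_a" else 1
        mask = (t >= bp) & (branch == which)
        lo, hi = bp, 1.0
    elif isinstance(region, tuple) and len(region) == 3 and region[0] == "interval":
        _, lo, hi = region
        mask = (t >= lo) & (t <= hi)
    else:
        raise ValueError(f"unknown region descriptor {region!r}")
    span = hi - lo if hi > lo else 1.0
    t_rel = np.clip((t - lo) / span, 0.0, 1.0)
    return mask, t_rel


def _effect(effect: str, t_rel: np.ndarray) -> np.ndarray:
    if effect == "linear":
        return t_rel
    # sigmoidal ramp of unit amplitude, steepness 10, centered mid-region
    return 1.0 / (1.0 + np.exp(-10.0 * (t_rel - 0.5)))


def generate(spec: SyntheticSpec):
    """Generate (ExpressionMatrix, Embedding, ground-truth table).

    The ground-truth table lists each planted gene's id, region, effect
    shape and slope (amplitude).
    """
    from .io_formats import Embedding, ExpressionMatrix

    t, branch, coords = _embedding(spec)
    C, G = spec.n_cells, spec.n_genes

    rng_noise = np.random.default_rng([spec.seed, _NOISE])
    X = spec.baseline + spec.noise_sd * rng_noise.standard_normal((C, G))
    for pg in spec.planted_genes:
        mask, t_rel = _region_mask(spec, pg.region, t, branch)
        X[mask, pg.gene_index] += pg.slope * _effect(pg.effect, t_rel[mask])
    np.clip(X, 0.0, None, out=X)

    if spec.counts_mode:
        rng_counts = np.random.default_rng([spec.seed, _COUNTS])
        lam = np.expm1(X)
        X = np.log1p(rng_counts.poisson(lam).astype(np.float64))

    if spec.dropout_rate > 0:
        rng_drop = np.random.default_rng([spec.seed, _DROPOUT])
        X[rng_drop.uniform(size=(C, G)) < spec.dropout_rate] = 0.0

    width_c = len(str(C))
    width_g = len(str(G))
    cell_ids = [f"cell{i:0{width_c}d}" for i in range(C)]
    gene_ids = [f"gene{i:0{width_g}d}" for i in range(G)]
    dim_names = [f"DC{p + 1}" for p in range(coords.shape[1])]

    expr = ExpressionMatrix(values=X, cell_ids=cell_ids, gene_ids=gene_ids)
    emb = Embedding(coords=coords, dim_names=dim_names, cell_ids=cell_ids)
    truth = pd.DataFrame(
        {
            "gene": [gene_ids[pg.gene_index] for pg in spec.planted_genes],
            "region": [
                f"interval:{r[1]}:{r[2]}" if isinstance(r := pg.region, tuple) else pg.region
                for pg in spec.planted_genes
            ],
            "effect": [pg.effect for pg in spec.planted_genes],
            "slope": [pg.slope for pg in spec.planted_genes],
        }
    )
    return expr, emb, truth


def parse_spec_file(path) -> SyntheticSpec:
    """Parse a small key=value spec file.

    Recognized keys: n_cells, n_genes, embedding_kind, dropout_rate,
    noise_sd, baseline, branch_point, counts_mode, seed, and ``planted`` —
    a semicolon-separated list of ``index:region:effect:slope`` entries
    where region may be ``all``, ``trunk``, ``branch_a``, ``branch_b`` or
    ``interval:lo:hi``.  Lines starting with ``#`` are ignored.
    """
    kwargs: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"cannot parse spec line: {line!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key in ("n_cells", "n_genes", "seed"):
                kwargs[key] = int(val)
            elif key in ("dropout_rate", "noise_sd", "baseline", "branch_point"):
                kwargs[key] = float(val)
            elif key == "embedding_kind":
                kwargs[key] = val
            elif key == "counts_mode":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key == "planted":
                planted = []
                for entry in filter(None, (e.strip() for e in val.split(";"))):
                    parts = entry.split(":")
                    if parts[1] == "interval":
                        region: object = ("interval", float(parts[2]), float(parts[3]))
                        effect, slope = parts[4], float(parts[5])
                    else:
                        region, effect, slope = parts[1], parts[2], float(parts[3])
                    planted.append(PlantedGene(int(parts[0]), region, effect, slope))
                kwargs["planted_genes"] = tuple(planted)
            else:
                raise ValueError(f"unknown spec key {key!r}")
    return SyntheticSpec(**kwargs)
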