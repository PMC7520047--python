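import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import generelevance as gr

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expr(rng):
    """8 cells × 5 genes, strictly positive continuous values."""
    X = rng.lognormal(0.0, 0.5, size=(8, 5))
    return gr.ExpressionMatrix(
        values=X,
        cell_ids=[f"c{i}" for i in range(8)],
        gene_ids=[f"g{i}" for i in range(5)],
    )


@pytest.fixture
def small_emb(rng, small_expr):
    coords = rng.normal(size=(8, 2))
    return gr.Embedding(coords=coords, dim_names=["DC1", "DC2"], cell_ids=small_expr.cell_ids)


def _pipeline_ranks(spec):
    expr, emb, truth = gr.generate(spec)
    graph = gr.build_knn(expr, metric="spearman")
    diff = gr.estimate_differentials(expr, emb, graph)
    scores = gr.compute_scores(diff)
    ranks = gr.rank_genes_per_cell(scores)
    return {"expr": expr, "emb": emb, "truth": truth, "graph": graph,
            "scores": scores, "ranks": ranks}


@pytest.fixture(scope="session")
def benchmark_runs():
    """Full pipeline on the default synthetic benchmark for 20 seeds."""
    return {s: _pipeline_ranks(gr.SyntheticSpec.benchmark(seed=s)) for s in range(20)}


@pytest.fixture(scope="session")
def branch_runs():
    """Full pipeline on the branch-restricted benchmark for 20 seeds."""
    return {s: _pipeline_ranks(gr.SyntheticSpec.branch_benchmark(seed=s)) for s in range(20)}
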