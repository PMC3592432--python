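import numpy as np
import pytest

from clipper import synthetic
from clipper.datasets import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_graph():
    return synthetic.default_pathway_graph()


@pytest.fixture
def default_tree():
    return synthetic.default_junction_tree()


@pytest.fixture
def dataset_factory():
    """Build a small ExpressionDataset from explicit gene rows."""

    def make(rows: dict[str, list[float]], n1: int | None = None) -> ExpressionDataset:
        genes = list(rows)
        values = np.array([rows[g] for g in genes], dtype=float)
        n = values.shape[1]
        n1 = n // 2 if n1 is None else n1
        labels = np.array([0] * n1 + [1] * (n - n1))
        return ExpressionDataset(
            values, genes, [f"s{i}" for i in range(n)], labels
        )

    return make


@pytest.fixture
def null_dataset(default_graph):
    """One two-class draw from a single graphical Gaussian model."""
    K = synthetic.random_ggm(default_graph, 5)
    P = len(default_graph.nodes)
    sc = synthetic.Scenario(
        default_graph, np.zeros(P), np.zeros(P), K, K, 20, 20, 6
    )
    return synthetic.sample_scenario(sc)
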