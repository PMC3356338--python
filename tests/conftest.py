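import numpy as np
import pytest

from pathpower import GeneNetwork, GroupedExpression, Pathway, PathwayCollection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grouped(values, gene_ids=None):
    """Wrap a genes x (2m) matrix with equal control/treatment labels."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    assert n % 2 == 0
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(p)]
    labels = np.asarray(["control"] * (n // 2) + ["treatment"] * (n // 2))
    return GroupedExpression(values, gene_ids, labels)


@pytest.fixture
def tiny_data(rng):
    """10 genes, 5 + 5 samples of iid standard normal data."""
    return make_grouped(rng.standard_normal((10, 10)))


@pytest.fixture
def chain_graph():
    return GeneNetwork(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def single_pathway():
    return PathwayCollection([Pathway("pw1", ["g000", "g001", "g002"])])
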