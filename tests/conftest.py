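import numpy as np
import pytest

from protofrag.featurize import FeatureConfig
from protofrag.graphs import MolecularGraph
from protofrag.model import ModelConfig
from protofrag.synthetic import generate_dataset, planted_to_dataset


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def planted_small():
    """60 planted-motif graphs, 4 classes, fixed seed (fast fixture)."""
    return generate_dataset(n_graphs=60, n_motif_classes=4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(planted_small):
    return planted_to_dataset(planted_small, "classification")


@pytest.fixture(scope="session")
def feature_dims(small_dataset):
    g = small_dataset.graphs[0]
    return g.node_features.shape[1], g.edge_features.shape[1]


@pytest.fixture()
def tiny_model_config(feature_dims):
    d1, d2 = feature_dims
    return ModelConfig(node_dim=d1, edge_dim=d2, hidden_dim=16, num_layers=2,
                       n_classes=4, dropout=0.0, n_tasks=1,
                       task_type="classification")


def random_graph(rng: np.random.Generator, n: int, d1: int = 5, d2: int = 3,
                 p_edge: float = 0.5) -> MolecularGraph:
    """Random connected attributed graph for property tests."""
    edges = set()
    for v in range(1, n):  # random spanning tree keeps it connected
        u = int(rng.integers(v))
        edges.add((u, v))
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < p_edge:
                edges.add((u, v))
    E = np.array(sorted(edges), dtype=np.int64).reshape(-1, 2)
    return MolecularGraph(
        node_features=rng.normal(size=(n, d1)),
        edge_index=E,
        edge_features=rng.normal(size=(len(edges), d2)),
    )


def permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel nodes: new index perm[i] for old node i."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    new_edges = np.array([[min(perm[u], perm[v]), max(perm[u], perm[v])]
                          for u, v in g.edge_index], dtype=np.int64)
    order = np.lexsort((new_edges[:, 1], new_edges[:, 0]))
    return MolecularGraph(
        node_features=g.node_features[inv],
        edge_index=new_edges[order],
        edge_features=g.edge_features[order],
        mol_id=g.mol_id,
    )
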