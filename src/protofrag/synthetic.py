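"""Synthetic attributed graphs with planted substructure classes.

Emulates the structure the substructure-discovery model assumes in real
molecules: small connected motifs (stand-ins for functional groups) with
categorical node/edge attributes, joined by sparse single bridge edges, so
within-motif connectivity is dense relative to between-motif connectivity.
Each node carries a known motif-class label and each graph a label that is
a deterministic function of motif presence (classification) or of motif
counts (regression) — giving every training stage a ground truth without
external data.

Attributes are drawn from the molecular featurization vocabulary so the
generated graphs run through the same encoder as parsed molecules; they are
attribute-compatible stand-ins, not chemically valid molecules.

The template list deliberately includes an attribute-identical but
topology-distinct pair (a carbon path and a carbon triangle), so telling
those classes apart requires context, not node attributes alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .featurize import FeatureConfig, atom_feature_vector, bond_feature_vector
from .graphs import LabeledDataset, MolecularGraph

__all__ = ["MotifTemplate", "PlantedGraph", "DEFAULT_TEMPLATES",
           "generate_dataset", "planted_to_dataset", "adjusted_rand_index",
           "save_planted_json", "load_planted_json"]


@dataclass(frozen=True)
class MotifTemplate:
    """A small connected attributed subgraph used as a planted building block."""

    template_id: int
    elements: tuple                      # per-node element symbols
    edges: tuple                         # ((u, v, bond_type), ...)
    ring_edges: frozenset = frozenset()  # indices into ``edges`` lying on a cycle
    aromatic: bool = False

    def __post_init__(self):
        n = len(self.elements)
        if not 3 <= n <= 8:
            raise ValueError("motif templates must have 3–8 nodes")
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((u, v) for u, v, _ in self.edges)
        if not nx.is_connected(g):
            raise ValueError(f"motif template {self.template_id} is not connected")

    @property
    def n_nodes(self) -> int:
        return len(self.elements)


# Default motif vocabulary.  Templates 0 and 3 are the attribute-identical /
# topology-distinct pair: three single-bonded carbons as a path vs a triangle.
DEFAULT_TEMPLATES: tuple = (
    MotifTemplate(0, ("C", "C", "C"), ((0, 1, "SINGLE"), (1, 2, "SINGLE"))),
    MotifTemplate(1, ("C", "O", "O"), ((0, 1, "DOUBLE"), (0, 2, "SINGLE"))),
    MotifTemplate(2, ("N", "C", "C", "C"),
                  ((0, 1, "SINGLE"), (0, 2, "SINGLE"), (0, 3, "SINGLE"))),
    MotifTemplate(3, ("C", "C", "C"),
                  ((0, 1, "SINGLE"), (1, 2, "SINGLE"), (0, 2, "SINGLE")),
                  ring_edges=frozenset({0, 1, 2})),
    MotifTemplate(4, ("S", "C", "C"), ((0, 1, "SINGLE"), (1, 2, "DOUBLE"))),
    MotifTemplate(5, ("C", "C", "C", "C", "C", "C"),
                  tuple((i, (i + 1) % 6, "AROMATIC") for i in range(6)),
                  ring_edges=frozenset(range(6)), aromatic=True),
    MotifTemplate(6, ("N", "N", "C"), ((0, 1, "SINGLE"), (1, 2, "SINGLE"))),
    MotifTemplate(7, ("O", "C", "C", "O"),
                  ((0, 1, "SINGLE"), (1, 2, "SINGLE"), (2, 3, "SINGLE"),
                   (3, 0, "SINGLE")), ring_edges=frozenset(range(4))),
)


@dataclass
class PlantedGraph:
    graph: MolecularGraph
    node_class: np.ndarray          # (n,) planted motif-class label per node
    motif_multiset: list            # template ids used, in placement order
    label: float

    def __post_init__(self):
        self.node_class = np.asarray(self.node_class, dtype=np.int64)
        if self.node_class.shape[0] != self.graph.n_nodes:
            raise ValueError("node_class must cover every node")


def _build_graph(rng: np.random.Generator, motif_ids, templates,
                 cfg: FeatureConfig, mol_id: str) -> tuple[MolecularGraph, np.ndarray]:
    nodes = []       # (element, aromatic, class)
    edges = []       # (u, v, bond_type, ring_flag)
    offsets = []
    for tid in motif_ids:
        t = templates[tid]
        off = len(nodes)
        offsets.append(off)
        for el in t.elements:
            nodes.append((el, t.aromatic, tid))
        for k, (u, v, bt) in enumerate(t.edges):
            edges.append((off + u, off + v, bt, k in t.ring_edges))
    # single bridge edges between consecutive motifs keep the graph connected
    # while keeping inter-motif connectivity sparse
    for a in range(len(motif_ids) - 1):
        u = offsets[a] + int(rng.integers(templates[motif_ids[a]].n_nodes))
        v = offsets[a + 1] + int(rng.integers(templates[motif_ids[a + 1]].n_nodes))
        edges.append((u, v, "SINGLE", False))

    degree = np.zeros(len(nodes), dtype=np.int64)
    for u, v, _, _ in edges:
        degree[u] += 1
        degree[v] += 1
    X = np.stack([
        atom_feature_vector(cfg, element=el, degree=int(degree[i]),
                            hybridization="SP3" if not arom else "SP2",
                            aromatic=arom)
        for i, (el, arom, _) in enumerate(nodes)
    ])
    E = np.array([(min(u, v), max(u, v)) for u, v, _, _ in edges], dtype=np.int64)
    EF = np.stack([
        bond_feature_vector(cfg, bond_type=bt, conjugated=(bt == "AROMATIC"),
                            in_ring=ring)
        for _, _, bt, ring in edges
    ])
    g = MolecularGraph(node_features=X, edge_index=E, edge_features=EF,
                       mol_id=mol_id)
    classes = np.array([c for _, _, c in nodes], dtype=np.int64)
    return g, classes


def generate_dataset(n_graphs: int = 200, n_motif_classes: int = 4,
                     motifs_per_graph_range: tuple = (2, 4),
                     label_rule: str = "presence", label_class: int = 3,
                     regression_weights=None, noise_level: float = 0.0,
                     seed: int = 0,
                     feature_config: FeatureConfig | None = None
                     ) -> list[PlantedGraph]:
    """Sample planted-motif graphs with deterministic labels.

    ``label_rule``: "presence" → binary indicator that ``label_class``
    occurs in the motif multiset, flipped with probability ``noise_level``;
    "count_linear" → dot product of motif-class counts with
    ``regression_weights`` (defaults to 1..K) plus Gaussian noise of scale
    ``noise_level``.  Identical seeds reproduce identical datasets.
    """
    if n_motif_classes < 2:
        raise ValueError("need at least 2 motif classes")
    if n_motif_classes > len(DEFAULT_TEMPLATES):
        raise ValueError(f"at most {len(DEFAULT_TEMPLATES)} motif classes available")
    lo, hi = motifs_per_graph_range
    if lo < 1 or hi < lo:
        raise ValueError("motifs_per_graph_range must be (lo>=1, hi>=lo)")
    if label_rule == "presence" and not 0 <= label_class < n_motif_classes:
        raise ValueError("label_class outside the motif-class range")

    templates = DEFAULT_TEMPLATES[:n_motif_classes]
    cfg = feature_config or FeatureConfig()
    rng = np.random.default_rng(seed)
    if regression_weights is None:
        regression_weights = np.arange(1, n_motif_classes + 1, dtype=np.float64)
    out = []
    for i in range(n_graphs):
        k = int(rng.integers(lo, hi + 1))
        motif_ids = [int(rng.integers(n_motif_classes)) for _ in range(k)]
        g, classes = _build_graph(rng, motif_ids, templates, cfg, f"synthetic:{i}")
        if label_rule == "presence":
            y = float(label_class in motif_ids)
            if noise_level > 0 and rng.random() < noise_level:
                y = 1.0 - y
        elif label_rule == "count_linear":
            counts = np.bincount(motif_ids, minlength=n_motif_classes)
            y = float(counts @ np.asarray(regression_weights, dtype=np.float64))
            if noise_level > 0:
                y += float(rng.normal(scale=noise_level))
        else:
            raise ValueError(f"unknown label_rule {label_rule!r}")
        g.labels = np.array([y])
        g.label_mask = np.array([True])
        out.append(PlantedGraph(graph=g, node_class=classes,
                                motif_multiset=motif_ids, label=y))
    return out


def planted_to_dataset(planted: list[PlantedGraph],
                       task_type: str = "classification") -> LabeledDataset:
    return LabeledDataset([p.graph for p in planted], ["label"], task_type)


def adjusted_rand_index(planted, predicted) -> float:
    """Chance-corrected partition agreement; 1 = identical up to relabeling."""
    planted = np.asarray(planted)
    predicted = np.asarray(predicted)
    if planted.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(planted, predicted))


# ---- JSON round-trip (the graph format the CLI consumes) -----------------

def save_planted_json(path, planted: list[PlantedGraph],
                      task_type: str = "classification") -> None:
    records = []
    for p in planted:
        records.append({
            "mol_id": p.graph.mol_id,
            "node_features": p.graph.node_features.tolist(),
            "edge_index": p.graph.edge_index.tolist(),
            "edge_features": p.graph.edge_features.tolist(),
            "labels": None if p.graph.labels is None else p.graph.labels.tolist(),
            "node_class": p.node_class.tolist(),
            "motif_multiset": list(p.motif_multiset),
            "label": p.label,
        })
    with open(path, "w") as f:
        json.dump({"task_type": task_type, "graphs": records}, f)


def load_planted_json(path) -> tuple[list[PlantedGraph], str]:
    with open(path) as f:
        payload = json.load(f)
    planted = []
    for r in payload["graphs"]:
        g = MolecularGraph(node_features=np.array(r["node_features"]),
                           edge_index=np.array(r["edge_index"]),
                           edge_features=np.array(r["edge_features"]),
                           labels=None if r["labels"] is None
                           else np.array(r["labels"]),
                           mol_id=r["mol_id"])
        planted.append(PlantedGraph(graph=g,
                                    node_class=np.array(r["node_class"]),
                                    motif_multiset=r["motif_multiset"],
                                    label=r["label"]))
    return planted, payload["task_type"]
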