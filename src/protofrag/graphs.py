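"""In-memory containers for attributed molecular graphs and datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MolecularGraph", "LabeledDataset"]


@dataclass
class MolecularGraph:
    """An undirected attributed graph: atoms as nodes, bonds as edges.

    ``edge_index`` stores each unordered edge once as ``(u, v)`` with
    ``u < v``; message passing expands both directions.  Labels are optional
    per-task values with a boolean mask marking observed entries.
    """

    node_features: np.ndarray            # (n, d1)
    edge_index: np.ndarray               # (|E|, 2) int, one row per unordered edge
    edge_features: np.ndarray            # (|E|, d2)
    labels: np.ndarray | None = None     # (T,) float, NaN allowed where masked out
    label_mask: np.ndarray | None = None  # (T,) bool
    mol_id: str = ""

    adjacency: np.ndarray = field(init=False, repr=False)
    degrees: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        self.edge_features = np.asarray(self.edge_features, dtype=np.float64)
        n = self.node_features.shape[0]
        if n < 1:
            raise ValueError("a molecular graph needs at least one node")
        if self.edge_features.shape[0] != self.edge_index.shape[0]:
            raise ValueError("edge_features rows must match edge count")
        A = np.zeros((n, n), dtype=np.float64)
        for u, v in self.edge_index:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) out of range for n={n}")
            if u == v:
                raise ValueError("self-loops are not allowed")
            A[u, v] = 1.0
            A[v, u] = 1.0
        self.adjacency = A
        self.degrees = A.sum(axis=1).astype(np.int64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.float64).reshape(-1)
            if self.label_mask is None:
                self.label_mask = ~np.isnan(self.labels)
            else:
                self.label_mask = np.asarray(self.label_mask, dtype=bool).reshape(-1)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]

    # edge count m = |E| in the modularity normalization
    @property
    def edge_count(self) -> int:
        return self.n_edges

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Both directions of every edge: (src, dst, edge_feature_row_index)."""
        if self.n_edges == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z, z
        u, v = self.edge_index[:, 0], self.edge_index[:, 1]
        src = np.concatenate([u, v])
        dst = np.concatenate([v, u])
        eid = np.concatenate([np.arange(self.n_edges)] * 2)
        return src, dst, eid


@dataclass
class LabeledDataset:
    """An ordered collection of graphs sharing feature dims and task arity."""

    graphs: list[MolecularGraph]
    task_names: list[str]
    task_type: str  # "classification" | "regression"

    def __post_init__(self):
        if self.task_type not in ("classification", "regression"):
            raise ValueError(f"unknown task_type {self.task_type!r}")
        if self.graphs:
            d1 = self.graphs[0].node_features.shape[1]
            d2 = self.graphs[0].edge_features.shape[1] if self.graphs[0].n_edges else None
            for g in self.graphs:
                if g.node_features.shape[1] != d1:
                    raise ValueError("all graphs must share node feature dimension")
                if d2 is not None and g.n_edges and g.edge_features.shape[1] != d2:
                    raise ValueError("all graphs must share edge feature dimension")

    def __len__(self) -> int:
        return len(self.graphs)

    def __getitem__(self, i: int) -> MolecularGraph:
        return self.graphs[i]

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.graphs[i] for i in indices],
                              self.task_names, self.task_type)

    def label_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (N, T) labels and mask; unlabeled graphs get all-masked rows."""
        N, T = len(self.graphs), self.n_tasks
        y = np.full((N, T), np.nan)
        m = np.zeros((N, T), dtype=bool)
        for i, g in enumerate(self.graphs):
            if g.labels is not None and T:
                y[i] = g.labels
                m[i] = g.label_mask
        return y, m
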