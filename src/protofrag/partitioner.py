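"""Soft assignment of encoded nodes to K global substructure classes.

The partitioner is a small MLP over node embeddings followed by a
temperature-scaled softmax, giving each atom a probability distribution
over K substructure classes shared across the whole dataset.  Atoms of a
molecule landing in the same class form one substructure instance, whose
embedding is the probability-weighted mean of its member nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import MLP

__all__ = ["AssignmentMatrix", "SubstructureEmbeddings", "Partitioner",
           "assign_nodes", "pool_substructures", "hard_assignments",
           "EPS_PRESENCE"]

# minimum total probability mass for a class to count as present in a graph;
# guards the division in the weighted-mean pooling
EPS_PRESENCE = 1e-6


@dataclass
class AssignmentMatrix:
    """Row-stochastic n×K soft node-to-class assignment."""

    S: Tensor                    # (n, K), rows on the probability simplex
    tau1: float
    K: int = field(init=False)

    def __post_init__(self):
        self.S = as_tensor(self.S)
        self.K = self.S.shape[1]
        rowsums = self.S.data.sum(axis=1)
        if np.any(self.S.data < -1e-12) or np.any(np.abs(rowsums - 1.0) > 1e-6):
            raise ValueError("assignment rows must be nonnegative and sum to 1")

    @property
    def values(self) -> np.ndarray:
        return self.S.data

    @property
    def n_nodes(self) -> int:
        return self.S.shape[0]


@dataclass
class SubstructureEmbeddings:
    """K×d class-pooled embeddings with a per-class presence mask."""

    Z: Tensor                      # (K, d); absent-class rows are zero
    presence_mask: np.ndarray      # (K,) bool
    graph_id: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.Z.data


class Partitioner:
    """Two-layer MLP + temperature softmax producing assignment matrices."""

    def __init__(self, hidden_dim: int, n_classes: int,
                 rng: np.random.Generator, tau1: float = 1.0,
                 mlp_hidden: int | None = None):
        if tau1 <= 0:
            raise ValueError(f"temperature tau1 must be positive, got {tau1}")
        if n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        self.n_classes = n_classes
        self.tau1 = tau1
        self.params: dict[str, Tensor] = {}
        width = mlp_hidden if mlp_hidden is not None else hidden_dim
        self.mlp = MLP(rng, [hidden_dim, width, n_classes], self.params,
                       "part.mlp", activation=lambda t: t.elu())

    def logits(self, H: Tensor) -> Tensor:
        return self.mlp(as_tensor(H))

    def __call__(self, H: Tensor) -> AssignmentMatrix:
        return assign_nodes(H, self.tau1, self)


def assign_nodes(H: Tensor, tau1: float, partitioner: Partitioner) -> AssignmentMatrix:
    """S = softmax(MLP(H) / tau1) row-wise; tau1 controls peakedness."""
    if tau1 <= 0:
        raise ValueError(f"temperature tau1 must be positive, got {tau1}")
    logits = partitioner.logits(as_tensor(H))
    S = (logits * (1.0 / tau1)).softmax(axis=1)
    return AssignmentMatrix(S=S, tau1=tau1)


def pool_substructures(assignment: AssignmentMatrix, H: Tensor,
                       graph_id: str = "",
                       mode: str = "soft") -> SubstructureEmbeddings:
    """Per-class mean of node embeddings under the soft assignment.

    ``mode="soft"``: Z = (Sᵀ H) ⊘ rep(Sᵀ·1, d) — every node contributes to
    every class with its assignment probability; classes whose total mass is
    below ``EPS_PRESENCE`` get a zero row and a false presence flag.

    ``mode="member"``: average pooling of the nodes *inside* each
    substructure — only a class's argmax members contribute (with their soft
    weights renormalized), and a class with no members is absent (zero row).
    A substructure instance is thereby the set of atoms whose top class it
    is, so classes that do not appear in the molecule are naturally zero
    vectors, and the pooled embedding is a genuine mean of member nodes
    rather than a mixture over the whole molecule.
    """
    H = as_tensor(H)
    S = assignment.S
    if S.shape[0] != H.shape[0]:
        raise ValueError("assignment and embeddings disagree on node count")
    if mode == "soft":
        weights = S
    elif mode == "member":
        members = np.zeros(S.shape)
        members[np.arange(S.shape[0]), np.argmax(S.data, axis=1)] = 1.0
        weights = S * members
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    masses = weights.sum(axis=0)                 # (K,)
    present = masses.data >= EPS_PRESENCE
    safe = masses.clip_min(EPS_PRESENCE)
    Z = (weights.T @ H) / safe.reshape(-1, 1)
    Z = Z * present.astype(np.float64).reshape(-1, 1)  # zero absent rows
    return SubstructureEmbeddings(Z=Z, presence_mask=present, graph_id=graph_id)


def hard_assignments(assignment: AssignmentMatrix) -> np.ndarray:
    """Per-node argmax class; ties break toward the lowest class index."""
    return np.argmax(assignment.values, axis=1).astype(np.int64)
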