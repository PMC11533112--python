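"""Self-supervised pre-training objectives.

Two families of losses shape the partitioner:

* **Connectivity**: a relaxed-modularity reward (substructures should be
  tightly connected relative to a degree-preserving random graph) plus an
  orthogonality penalty on class masses that rules out the degenerate
  all-in-one-class partition.

* **Prototypical contrastive clustering**: every substructure instance is
  pulled toward the momentum-updated prototype of its class and pushed away
  from the other prototypes (InfoNCE over cosine similarities), with an
  additional intra-class compactness term.

Conventions: modularity is a quantity to *maximize*; the connectivity loss
uses its negation so that every term here is minimized.  Prototypes are
non-parametric — no gradient flows into the bank, which is refreshed after
each optimizer step from batch class means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate
from .graphs import MolecularGraph
from .partitioner import AssignmentMatrix, SubstructureEmbeddings

__all__ = ["LossWeights", "PrototypeBank", "PrototypeStateError",
           "modularity", "orthogonality_loss", "cosine_similarity",
           "update_prototypes", "prototype_contrastive_loss",
           "compactness_loss", "self_supervised_loss"]

_NORM_FLOOR = 1e-12


class PrototypeStateError(RuntimeError):
    pass


@dataclass
class LossWeights:
    """Trade-off weights of the self-supervised objective.

    alpha weights orthogonality inside the connectivity loss, beta weights
    compactness inside the clustering loss, gamma balances clustering vs
    connectivity, tau2 is the contrastive temperature.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.5
    tau2: float = 0.1

    def __post_init__(self):
        if self.tau2 <= 0:
            raise ValueError("tau2 must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class PrototypeBank:
    """K momentum-updated non-parametric class prototypes."""

    n_classes: int
    dim: int
    momentum: float = 0.99
    P: np.ndarray = field(default=None)
    initialized: np.ndarray = field(default=None)

    def __post_init__(self):
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if self.P is None:
            self.P = np.zeros((self.n_classes, self.dim))
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.initialized is None:
            self.initialized = np.zeros(self.n_classes, dtype=bool)
        self.initialized = np.asarray(self.initialized, dtype=bool)

    @property
    def all_initialized(self) -> bool:
        return bool(self.initialized.all())


def modularity(assignment: AssignmentMatrix, graph: MolecularGraph) -> Tensor:
    """Relaxed modularity (1/2m)·Tr(Sᵀ(A − ddᵀ/2m)S) of a soft partition.

    Positive when classes are denser than the configuration-model
    expectation.  Edgeless graphs have no connectivity signal; their
    modularity is defined as 0 (with a warning).
    """
    m = graph.edge_count
    if m == 0:
        warnings.warn("modularity of an edgeless graph is defined as 0")
        return Tensor(0.0)
    d = graph.degrees.astype(np.float64)
    B = (graph.adjacency - np.outer(d, d) / (2.0 * m)) / (2.0 * m)
    S = assignment.S
    return (S * (Tensor(B) @ S)).sum()


def orthogonality_loss(assignment: AssignmentMatrix) -> Tensor:
    """Class-mass balance penalty (√K/n)·‖Σᵢ sᵢ‖ − 1.

    Zero exactly when every class holds n/K probability mass; bounded below
    by 0 since ‖·‖₂ ≥ ‖·‖₁/√K = n/√K for a row-stochastic S.
    """
    S = assignment.S
    n, K = S.shape
    return (np.sqrt(K) / n) * S.sum(axis=0).norm() - 1.0


def cosine_similarity(u, v) -> Tensor:
    """uᵀv / (‖u‖‖v‖); raises for zero vectors (mask absent slots first)."""
    u, v = as_tensor(u), as_tensor(v)
    nu = float(np.linalg.norm(u.data))
    nv = float(np.linalg.norm(v.data))
    if nu < _NORM_FLOOR or nv < _NORM_FLOOR:
        raise ValueError("cosine similarity undefined for zero vectors")
    return (u * v).sum() / (u.norm() * v.norm())


def update_prototypes(bank: PrototypeBank,
                      Z_batch: list[SubstructureEmbeddings]) -> PrototypeBank:
    """Momentum update p_c ← μ·p_c + (1−μ)·(batch mean of class-c instances).

    A class's first-ever batch appearance sets the prototype to the batch
    mean directly; classes absent from the batch are left untouched.  Stops
    gradient: operates on raw arrays.
    """
    if not Z_batch:
        raise ValueError("prototype update needs a nonempty batch")
    mu = bank.momentum
    for c in range(bank.n_classes):
        rows = [z.values[c] for z in Z_batch if z.presence_mask[c]]
        if not rows:
            continue
        p_tilde = np.mean(rows, axis=0)
        if bank.initialized[c]:
            bank.P[c] = mu * bank.P[c] + (1.0 - mu) * p_tilde
        else:
            bank.P[c] = p_tilde
            bank.initialized[c] = True
    return bank


def _stack_present(Z_batch: list[SubstructureEmbeddings]
                   ) -> tuple[Tensor, np.ndarray] | tuple[None, None]:
    """All present substructure instances stacked (I×d) with class ids (I,)."""
    parts, classes = [], []
    for z in Z_batch:
        idx = np.flatnonzero(z.presence_mask)
        if idx.size:
            parts.append(z.Z[idx])
            classes.append(idx)
    if not parts:
        return None, None
    return concatenate(parts, axis=0), np.concatenate(classes)


def _similarity_matrix(Zc: Tensor, bank: PrototypeBank) -> Tensor:
    """Cosine similarities of stacked instances against all prototypes."""
    norms = (Zc * Zc).sum(axis=1, keepdims=True).clip_min(_NORM_FLOOR).sqrt()
    Zn = Zc / norms
    Pn = bank.P / np.maximum(np.linalg.norm(bank.P, axis=1, keepdims=True),
                             _NORM_FLOOR)
    return Zn @ Tensor(Pn.T)


def prototype_contrastive_loss(Z_batch: list[SubstructureEmbeddings],
                               bank: PrototypeBank, tau2: float) -> Tensor:
    """InfoNCE over cosine similarities to the K prototypes.

    Mean over present instances of −log softmax(s(z,·)/τ₂)[c]; the positive
    is the instance's own class slot.  K=1 gives 0 (no negatives).
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    if not bank.all_initialized:
        raise PrototypeStateError(
            "all prototypes must be initialized before the contrastive loss")
    Zc, classes = _stack_present(Z_batch)
    if Zc is None:
        return Tensor(0.0)
    sims = _similarity_matrix(Zc, bank)
    log_probs = (sims * (1.0 / tau2)).log_softmax(axis=1)
    onehot = np.zeros(sims.shape)
    onehot[np.arange(classes.size), classes] = 1.0
    return -(log_probs * onehot).sum(axis=1).mean()


def compactness_loss(Z_batch: list[SubstructureEmbeddings],
                     bank: PrototypeBank) -> Tensor:
    """Mean over present instances of (1 − s(z, p_c))²."""
    if not bank.all_initialized:
        raise PrototypeStateError(
            "all prototypes must be initialized before the compactness loss")
    Zc, classes = _stack_present(Z_batch)
    if Zc is None:
        return Tensor(0.0)
    sims = _similarity_matrix(Zc, bank)
    onehot = np.zeros(sims.shape)
    onehot[np.arange(classes.size), classes] = 1.0
    picked = (sims * onehot).sum(axis=1)
    return ((1.0 - picked) ** 2).mean()


def self_supervised_loss(graph_batch: list[MolecularGraph],
                         S_batch: list[AssignmentMatrix],
                         Z_batch: list[SubstructureEmbeddings],
                         bank: PrototypeBank,
                         weights: LossWeights,
                         include_connectivity: bool = True,
                         include_clustering: bool = True,
                         orthogonality: str = "batch",
                         ) -> tuple[Tensor, dict]:
    """γ·(L_p + β·L_d) + (1−γ)·(−modularity + α·L_o), batch-averaged.

    Returns the total loss tensor and a float breakdown of the components.
    The include_* switches implement the pre-training ablations (a dropped
    family contributes 0 but keeps the γ weighting intact).

    ``orthogonality`` sets the scope of the balance penalty: "batch"
    (default) evaluates it on the node assignments of the whole batch, so
    class usage must balance across molecules while any single molecule is
    free to use only the few classes its substructures need; "graph"
    averages the per-molecule penalties, which additionally pushes every
    molecule to spread its atoms over all K classes.
    """
    if not (len(graph_batch) == len(S_batch) == len(Z_batch)):
        raise ValueError("batch lists must be aligned")
    B = len(graph_batch)
    if B == 0:
        raise ValueError("empty batch")

    zero = Tensor(0.0)
    if include_connectivity:
        mod_terms = [modularity(S, g) for S, g in zip(S_batch, graph_batch)]
        mod = sum(mod_terms[1:], mod_terms[0]) * (1.0 / B)
        if orthogonality == "batch":
            S_cat = concatenate([S.S for S in S_batch], axis=0)
            orth = orthogonality_loss(
                AssignmentMatrix(S=S_cat, tau1=S_batch[0].tau1))
        elif orthogonality == "graph":
            orth_terms = [orthogonality_loss(S) for S in S_batch]
            orth = sum(orth_terms[1:], orth_terms[0]) * (1.0 / B)
        else:
            raise ValueError(f"unknown orthogonality scope {orthogonality!r}")
        L_con = -mod + weights.alpha * orth
    else:
        mod, orth, L_con = zero, zero, zero

    if include_clustering:
        L_p = prototype_contrastive_loss(Z_batch, bank, weights.tau2)
        L_d = compactness_loss(Z_batch, bank)
        L_clu = L_p + weights.beta * L_d
    else:
        L_p, L_d, L_clu = zero, zero, zero

    total = weights.gamma * L_clu + (1.0 - weights.gamma) * L_con
    breakdown = {
        "L_p": float(L_p.data), "L_d": float(L_d.data),
        "modularity": float(mod.data), "L_o": float(orth.data),
        "L_con": float(L_con.data), "L_clu": float(L_clu.data),
        "L_ss": float(total.data),
    }
    return total, breakdown
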