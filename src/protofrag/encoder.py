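"""Attention-based message-passing encoder for attributed molecular graphs.

Each layer aggregates neighbour messages with edge-feature-aware attention
(the attention-MPNN family used throughout molecular property prediction)
and updates node states with an ELU-gated affine transform.  The encoder is
permutation-equivariant: relabelling the nodes of the input graph permutes
the rows of the output embedding matrix identically.

Mini-batches are handled by block-diagonal stacking: node features of all
graphs are concatenated and directed edges are offset, so one forward pass
encodes a whole batch with no cross-graph edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, segment_softmax, segment_sum
from .graphs import MolecularGraph
from .nn import Linear, glorot

__all__ = ["EncoderConfig", "GraphBatch", "GraphEncoder", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    hidden_dim: int = 128
    num_layers: int = 3
    attention_heads: int = 1
    dropout: float = 0.1
    use_edge_features: bool = True

    def __post_init__(self):
        if self.hidden_dim < 1 or self.num_layers < 1 or self.attention_heads < 1:
            raise ConfigError("hidden_dim, num_layers, attention_heads must be >= 1")


@dataclass
class GraphBatch:
    """Block-diagonal stacking of a list of graphs for one forward pass."""

    graphs: list[MolecularGraph]
    node_features: np.ndarray = field(init=False)     # (n_total, d1)
    edge_features: np.ndarray = field(init=False)     # (E_dir, d2)
    src: np.ndarray = field(init=False)               # (E_dir,) global node ids
    dst: np.ndarray = field(init=False)
    node_slices: list = field(init=False)             # [(lo, hi)] per graph
    graph_index: np.ndarray = field(init=False)       # (n_total,) graph id per node

    def __post_init__(self):
        xs, efs, srcs, dsts, slices, gidx = [], [], [], [], [], []
        offset = 0
        for gi, g in enumerate(self.graphs):
            s, d, eid = g.directed_edges()
            xs.append(g.node_features)
            efs.append(g.edge_features[eid] if g.n_edges
                       else np.zeros((0, g.edge_features.shape[1])))
            srcs.append(s + offset)
            dsts.append(d + offset)
            slices.append((offset, offset + g.n_nodes))
            gidx.append(np.full(g.n_nodes, gi, dtype=np.int64))
            offset += g.n_nodes
        self.node_features = np.concatenate(xs, axis=0)
        self.edge_features = np.concatenate(efs, axis=0)
        self.src = np.concatenate(srcs)
        self.dst = np.concatenate(dsts)
        self.node_slices = slices
        self.graph_index = np.concatenate(gidx)

    @property
    def n_total(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_graphs(self) -> int:
        return len(self.graphs)


class GraphEncoder:
    """Edge-conditioned attention MPNN producing n×d node embeddings."""

    def __init__(self, config: EncoderConfig, node_dim: int, edge_dim: int,
                 rng: np.random.Generator):
        self.config = config
        self.node_dim = node_dim
        self.edge_dim = edge_dim
        self.params: dict[str, Tensor] = {}
        d = config.hidden_dim
        self.lin_in = Linear(rng, node_dim, d, self.params, "enc.in")
        if config.use_edge_features:
            self.lin_edge = Linear(rng, edge_dim, d, self.params, "enc.edge")
        self.layers = []
        for l in range(config.num_layers):
            layer = {
                "W": Linear(rng, d, d, self.params, f"enc.l{l}.W", bias=False),
                "self": Linear(rng, d, d, self.params, f"enc.l{l}.self"),
                "a_dst": [], "a_src": [],
            }
            for h in range(config.attention_heads):
                a_d = glorot(rng, d, 1, shape=(d,))
                a_s = glorot(rng, d, 1, shape=(d,))
                self.params[f"enc.l{l}.h{h}.a_dst"] = a_d
                self.params[f"enc.l{l}.h{h}.a_src"] = a_s
                layer["a_dst"].append(a_d)
                layer["a_src"].append(a_s)
            self.layers.append(layer)

    def forward(self, batch: GraphBatch, training: bool = False,
                dropout_rng: np.random.Generator | None = None) -> Tensor:
        """Node embeddings (n_total × d) for a block-diagonal batch."""
        if batch.node_features.shape[1] != self.node_dim:
            raise ConfigError(
                f"node feature dim {batch.node_features.shape[1]} does not match "
                f"encoder input dim {self.node_dim}")
        cfg = self.config
        n = batch.n_total
        H = self.lin_in(Tensor(batch.node_features)).elu()

        has_edges = batch.src.size > 0
        if has_edges and cfg.use_edge_features:
            if batch.edge_features.shape[1] != self.edge_dim:
                raise ConfigError("edge feature dim mismatch")
            E = self.lin_edge(Tensor(batch.edge_features)).elu()

        for layer in self.layers:
            if has_edges:
                key = H[batch.src]
                if cfg.use_edge_features:
                    key = key + E
                key_t = layer["W"](key)
                Hd = layer["W"](H)
                agg = None
                for a_d, a_s in zip(layer["a_dst"], layer["a_src"]):
                    score = ((Hd[batch.dst] * a_d).sum(axis=1)
                             + (key_t * a_s).sum(axis=1)).leaky_relu(0.2)
                    alpha = segment_softmax(score, batch.dst, n)
                    msg = alpha.reshape(-1, 1) * key_t
                    part = segment_sum(msg, batch.dst, n)
                    agg = part if agg is None else agg + part
                agg = agg * (1.0 / cfg.attention_heads)
                H = (layer["self"](H) + agg).elu()
            else:
                H = layer["self"](H).elu()
            if training and cfg.dropout > 0:
                rng = dropout_rng if dropout_rng is not None else np.random.default_rng()
                mask = (rng.random(H.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                H = H * mask
        return H

    def encode(self, graph: MolecularGraph) -> Tensor:
        """Embeddings for a single graph (inference-style, no dropout)."""
        return self.forward(GraphBatch([graph]), training=False)
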