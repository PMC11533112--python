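"""Model assembly: partition model (pre-training) and property model.

``PartitionModel`` couples the message-passing encoder, the soft
partitioner and the prototype bank — everything the self-supervised stage
trains.  ``PropertyModel`` adds the cross-scale attention head and the
task MLP for supervised fine-tuning.  Both serialize to a single ``.npz``
checkpoint embedding a JSON config fingerprint, so an incompatible
checkpoint is rejected at load time rather than producing shape errors
mid-training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concatenate, segment_sum
from .encoder import EncoderConfig, GraphBatch, GraphEncoder, ConfigError
from .graphs import MolecularGraph
from .head import AttentionParams, PredictionHead, batched_cross_scale_attention
from .objectives import PrototypeBank
from .partitioner import (AssignmentMatrix, Partitioner, SubstructureEmbeddings,
                          hard_assignments, pool_substructures)

__all__ = ["ModelConfig", "PartitionModel", "PropertyModel",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    node_dim: int
    edge_dim: int
    hidden_dim: int = 128
    num_layers: int = 3
    attention_heads: int = 1
    dropout: float = 0.1
    use_edge_features: bool = True
    n_classes: int = 8            # K, global substructure class count
    tau1: float = 1.0
    momentum: float = 0.99        # prototype EMA coefficient
    pooling: str = "member"       # substructure pooling: "member" | "soft"
    # fine-tuning head
    n_tasks: int = 1
    task_type: str = "classification"
    readout_mode: str = "mean"
    cross_attention_heads: int = 4  # M
    use_attention: bool = True

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(hidden_dim=self.hidden_dim,
                             num_layers=self.num_layers,
                             attention_heads=self.attention_heads,
                             dropout=self.dropout,
                             use_edge_features=self.use_edge_features)

    def fingerprint(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


class PartitionModel:
    """Encoder + partitioner + prototype bank (the pre-trained network)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.tau1 = config.tau1  # live value; training may anneal it
        self.encoder = GraphEncoder(config.encoder_config(), config.node_dim,
                                    config.edge_dim, rng)
        self.partitioner = Partitioner(config.hidden_dim, config.n_classes,
                                       rng, tau1=config.tau1)
        self.bank = PrototypeBank(config.n_classes, config.hidden_dim,
                                  momentum=config.momentum)
        self.params: dict[str, Tensor] = {}
        self.params.update(self.encoder.params)
        self.params.update(self.partitioner.params)

    def forward_batch(self, graphs: list[MolecularGraph], training: bool = False,
                      dropout_rng: np.random.Generator | None = None,
                      pool_stopgrad: bool = False
                      ) -> tuple[GraphBatch, Tensor, list[AssignmentMatrix],
                                 list[SubstructureEmbeddings]]:
        """Encode, assign and pool a batch of graphs.

        With ``pool_stopgrad`` the node-embedding operand of the pooling is
        detached, so losses on the pooled substructure embeddings train the
        partitioner (through S) but cannot warp the encoder's embedding
        space directly; used by the clustering objective in pre-training.
        """
        batch = GraphBatch(graphs)
        H = self.encoder.forward(batch, training=training, dropout_rng=dropout_rng)
        S_full = ((self.partitioner.logits(H)) * (1.0 / self.tau1)
                  ).softmax(axis=1)
        H_pool = Tensor(H.data) if pool_stopgrad else H
        S_list, Z_list = [], []
        for (lo, hi), g in zip(batch.node_slices, graphs):
            S_g = AssignmentMatrix(S=S_full[slice(lo, hi)], tau1=self.tau1)
            S_list.append(S_g)
            Z_list.append(pool_substructures(S_g, H_pool[slice(lo, hi)],
                                             graph_id=g.mol_id,
                                             mode=self.config.pooling))
        return batch, H, S_list, Z_list

    def fragment(self, graph: MolecularGraph) -> dict:
        """Hard substructure assignment of one molecule (inference)."""
        from .autodiff import no_grad
        with no_grad():
            _, _, S_list, Z_list = self.forward_batch([graph])
        classes = hard_assignments(S_list[0])
        groups = {int(c): np.flatnonzero(classes == c).tolist()
                  for c in np.unique(classes)}
        return {
            "mol_id": graph.mol_id,
            "node_classes": classes.tolist(),
            "groups": groups,
            "present_classes": sorted(int(c) for c in np.unique(classes)),
        }


class PropertyModel:
    """PartitionModel + cross-scale attention + prediction head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 partition_model: PartitionModel | None = None):
        self.config = config
        self.partition = (partition_model if partition_model is not None
                          else PartitionModel(config, rng))
        d = config.hidden_dim
        self.params: dict[str, Tensor] = dict(self.partition.params)
        if config.use_attention:
            self.attention = AttentionParams(d, config.cross_attention_heads,
                                             rng, self.params, "att")
            rep_dim = d + config.cross_attention_heads * d
        else:
            self.attention = None
            rep_dim = d
        self.rep_dim = rep_dim
        self.head = PredictionHead(rep_dim, config.n_tasks, config.task_type,
                                   rng, params=self.params, prefix="head")

    @property
    def bank(self) -> PrototypeBank:
        return self.partition.bank

    def forward_batch(self, graphs: list[MolecularGraph], training: bool = False,
                      dropout_rng: np.random.Generator | None = None):
        """Returns (predictions, aux) where aux carries the pre-training
        intermediates (batch, S_list, Z_list, representation, attention maps)."""
        cfg = self.config
        batch, H, S_list, Z_list = self.partition.forward_batch(
            graphs, training=training, dropout_rng=dropout_rng)
        B = batch.n_graphs
        counts = np.array([g.n_nodes for g in graphs], dtype=np.float64)
        G = segment_sum(H, batch.graph_index, B)
        if cfg.readout_mode == "mean":
            G = G / counts.reshape(-1, 1)
        elif cfg.readout_mode != "sum":
            raise ConfigError(f"unknown readout mode {cfg.readout_mode!r}")

        theta = None
        if cfg.use_attention:
            Zflat = concatenate([z.Z for z in Z_list], axis=0)
            g_prime, theta = batched_cross_scale_attention(
                G, Zflat, cfg.n_classes, self.attention)
            g_G = concatenate([G, g_prime], axis=1)
        else:
            g_G = G
        preds = self.head.forward(g_G)
        aux = {"batch": batch, "S_list": S_list, "Z_list": Z_list,
               "representation": g_G, "attention": theta}
        return preds, aux

    def predict_dataset(self, graphs: list[MolecularGraph],
                        batch_size: int = 128) -> np.ndarray:
        """Positive-class probabilities (B, T) or regression values (B, T)."""
        from .autodiff import no_grad
        outs = []
        with no_grad():
            for i in range(0, len(graphs), batch_size):
                preds, _ = self.forward_batch(graphs[i:i + batch_size])
                if self.config.task_type == "classification":
                    outs.append(preds.data[:, :, 1])
                else:
                    outs.append(preds.data)
        return np.concatenate(outs, axis=0)


# ---- checkpointing -------------------------------------------------------

def save_checkpoint(path, model: PartitionModel | PropertyModel) -> None:
    """Serialize parameters + prototype bank + config fingerprint to .npz."""
    if isinstance(model, PropertyModel):
        bank = model.partition.bank
    else:
        bank = model.bank
    arrays = {f"param:{k}": v.data for k, v in model.params.items()}
    arrays["bank:P"] = bank.P
    arrays["bank:initialized"] = bank.initialized
    arrays["meta:kind"] = np.array(
        "property" if isinstance(model, PropertyModel) else "partition")
    arrays["meta:config"] = np.array(model.config.fingerprint())
    pm = model.partition if isinstance(model, PropertyModel) else model
    arrays["meta:tau1"] = np.array(pm.tau1)
    np.savez(path, **arrays)


def load_checkpoint(path, expect_kind: str | None = None
                    ) -> tuple[PartitionModel | PropertyModel, ModelConfig]:
    """Rebuild a model from a checkpoint; verifies the config fingerprint."""
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["meta:config"]))
        kind = str(data["meta:kind"])
        config = ModelConfig(**cfg_dict)
        if expect_kind is not None and kind != expect_kind:
            raise ConfigError(f"checkpoint is a {kind} model, expected {expect_kind}")
        rng = np.random.default_rng(0)  # params overwritten below
        model = (PropertyModel(config, rng) if kind == "property"
                 else PartitionModel(config, rng))
        for k, p in model.params.items():
            stored = data[f"param:{k}"]
            if stored.shape != p.data.shape:
                raise ConfigError(f"checkpoint shape mismatch for {k}")
            p.data = stored.copy()
        bank = model.bank if isinstance(model, PartitionModel) else model.partition.bank
        bank.P = data["bank:P"].copy()
        bank.initialized = data["bank:initialized"].copy()
        pm = model.partition if isinstance(model, PropertyModel) else model
        if "meta:tau1" in data:
            pm.tau1 = float(data["meta:tau1"])
    return model, config
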