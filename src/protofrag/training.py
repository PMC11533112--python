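"""Pre-training and fine-tuning loops.

Pre-training jointly optimizes the encoder and partitioner under the
self-supervised objective (connectivity + prototypical contrastive
clustering), refreshing the prototype bank once per batch after the
optimizer step.  Fine-tuning adds the cross-scale attention head, keeps
the self-supervised terms active at weight (1−λ), tracks the validation
metric with early stopping, and restores the best snapshot.

Adam with cosine learning-rate annealing and global-norm gradient clipping
throughout; all randomness flows from the config seed.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .graphs import LabeledDataset
from .head import masked_focal_loss, masked_mse, supervised_total_loss
from .model import ModelConfig, PartitionModel, PropertyModel
from .nn import Adam, clip_grad_norm, cosine_lr
from .objectives import LossWeights, self_supervised_loss, update_prototypes

__all__ = ["TrainConfig", "AblationFlags", "pretrain", "finetune", "evaluate",
           "aggregate_metric"]


@dataclass(frozen=True)
class AblationFlags:
    no_connectivity: bool = False   # drop modularity + orthogonality terms
    no_clustering: bool = False     # drop contrastive + compactness terms
    no_attention: bool = False      # predict from the global readout g alone


@dataclass
class TrainConfig:
    pretrain_epochs: int = 100
    finetune_epochs: int = 200
    patience: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    lr_floor: float = 1e-5
    weight_decay: float = 0.0
    grad_clip: float = 5.0
    lambda_sup: float = 0.5         # λ in the joint fine-tuning objective
    alpha_t: float = 0.25           # focal loss class weight
    freeze_prototypes: bool = False
    prototype_init: str = "kmeans"  # "kmeans" | "batch_means"
    # optionally detach node embeddings inside pooling for the pre-training
    # clustering terms: contrastive/compactness gradients then reshape the
    # partition only, never the embedding space
    clustering_stopgrad: bool = False
    # optional assignment-temperature annealing during pre-training (start
    # soft, end sharp); None keeps the model's tau1 fixed throughout
    tau1_start: float | None = None
    tau1_end: float | None = None
    seed: int = 0
    ablation: AblationFlags = field(default_factory=AblationFlags)

    def __post_init__(self):
        if self.pretrain_epochs < 1 or self.finetune_epochs < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _check_finite(value: float, context: str) -> None:
    if not math.isfinite(value):
        raise RuntimeError(f"divergent loss ({value}) during {context}; "
                           "lower the learning rate or check the inputs")


def _lazy_init_prototypes(bank, Z_list) -> None:
    # first-touch initialization: set still-empty prototypes to this batch's
    # class means without momentum-updating the already initialized ones
    for c in np.flatnonzero(~bank.initialized):
        rows = [z.values[c] for z in Z_list if z.presence_mask[c]]
        if rows:
            bank.P[c] = np.mean(rows, axis=0)
            bank.initialized[c] = True


def _kmeans_init_prototypes(bank, H: np.ndarray, seed: int) -> None:
    """Seed prototypes with k-means centroids of first-batch node embeddings.

    Early assignments are near-uniform, so batch class means all collapse to
    the global embedding mean and carry no class structure; centroids of the
    node-embedding clusters give the contrastive objective K genuinely
    distinct anchors from the start.
    """
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=bank.n_classes, n_init=4,
                random_state=seed % (2**31)).fit(H)
    bank.P[:] = km.cluster_centers_
    bank.initialized[:] = True


def pretrain(ds: LabeledDataset, cfg: TrainConfig, model_config: ModelConfig,
             weights: LossWeights | None = None,
             log_path=None, epoch_callback=None
             ) -> tuple[PartitionModel, list[dict]]:
    """Self-supervised pre-training; labels in ``ds`` are ignored.

    Returns the trained partition model and a per-epoch loss-breakdown
    history (also written as JSON lines when ``log_path`` is given).
    """
    if len(ds) == 0:
        raise ValueError("cannot pre-train on an empty dataset")
    weights = weights or LossWeights()
    rng = np.random.default_rng(cfg.seed)
    model = PartitionModel(model_config, rng)
    opt = Adam(model.params, lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    history: list[dict] = []
    log_f = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.pretrain_epochs):
            opt.lr = cosine_lr(epoch, cfg.pretrain_epochs, cfg.learning_rate,
                               cfg.lr_floor)
            if cfg.tau1_start is not None and cfg.tau1_end is not None:
                model.tau1 = cosine_lr(epoch, cfg.pretrain_epochs,
                                       cfg.tau1_start, cfg.tau1_end)
            sums: dict[str, float] = {}
            n_batches = 0
            for idx in _batches(len(ds), cfg.batch_size, rng):
                graphs = [ds.graphs[i] for i in idx]
                batch, H, S_list, Z_list = model.forward_batch(
                    graphs, training=True, dropout_rng=rng,
                    pool_stopgrad=cfg.clustering_stopgrad)
                include_clu = not cfg.ablation.no_clustering
                if include_clu and not model.bank.all_initialized:
                    if cfg.prototype_init == "kmeans":
                        _kmeans_init_prototypes(model.bank, H.data, cfg.seed)
                    else:
                        _lazy_init_prototypes(model.bank, Z_list)
                    include_clu = model.bank.all_initialized
                loss, breakdown = self_supervised_loss(
                    graphs, S_list, Z_list, model.bank, weights,
                    include_connectivity=not cfg.ablation.no_connectivity,
                    include_clustering=include_clu)
                _check_finite(breakdown["L_ss"], f"pre-training epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                clip_grad_norm(model.params, cfg.grad_clip)
                opt.step()
                if not cfg.ablation.no_clustering:
                    update_prototypes(model.bank, Z_list)
                for k, v in breakdown.items():
                    sums[k] = sums.get(k, 0.0) + v
                n_batches += 1
            rec = {"epoch": epoch,
                   **{k: v / n_batches for k, v in sums.items()}}
            history.append(rec)
            if log_f:
                log_f.write(json.dumps(rec) + "\n")
            if epoch_callback is not None:
                epoch_callback(epoch, model)
    finally:
        if log_f:
            log_f.close()
    return model, history


def evaluate(predictions: np.ndarray, labels: np.ndarray, task_type: str,
             mask: np.ndarray | None = None) -> dict:
    """Masked per-task ROC-AUC (averaged) for classification, RMSE otherwise.

    Classification tasks whose evaluation split lacks both classes are
    excluded from the average (reported in ``n_tasks_scored``).
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if predictions.ndim == 1:
        predictions = predictions[:, None]
    if labels.ndim == 1:
        labels = labels[:, None]
    if mask is None:
        mask = ~np.isnan(labels)
    mask = np.asarray(mask, dtype=bool)

    if task_type == "classification":
        aucs = []
        for t in range(labels.shape[1]):
            m = mask[:, t]
            y = labels[m, t]
            if m.sum() == 0 or len(np.unique(y)) < 2:
                continue
            aucs.append(roc_auc_score(y, predictions[m, t]))
        if not aucs:
            raise ValueError("no task had both classes in the evaluation split")
        return {"metric": "roc_auc", "value": float(np.mean(aucs)),
                "per_task": [float(a) for a in aucs],
                "n_tasks_scored": len(aucs)}
    if task_type == "regression":
        diff = (predictions - labels)[mask]
        return {"metric": "rmse", "value": float(np.sqrt(np.mean(diff**2))),
                "n_observed": int(mask.sum())}
    raise ValueError(f"unknown task_type {task_type!r}")


def _negative_proportion(ds: LabeledDataset, train_idx) -> np.ndarray:
    """Per-task fraction of negative labels in the training split (γ_t)."""
    y, m = ds.label_matrix()
    y, m = y[train_idx], m[train_idx]
    gammas = np.zeros(ds.n_tasks)
    for t in range(ds.n_tasks):
        obs = y[m[:, t], t]
        gammas[t] = float((obs == 0).mean()) if obs.size else 0.5
    return gammas


def finetune(partition_model: PartitionModel, ds: LabeledDataset,
             splits: tuple, cfg: TrainConfig,
             weights: LossWeights | None = None,
             log_path=None) -> tuple[PropertyModel, dict]:
    """Supervised fine-tuning on a labeled dataset with given index splits.

    The partition model's parameters continue to train (joint objective
    λ·L_sup + (1−λ)·L_ss); early stopping monitors validation ROC-AUC
    (max) or RMSE (min) and the best snapshot is restored before testing.
    """
    weights = weights or LossWeights()
    train_idx, valid_idx, test_idx = [list(s) for s in splits]
    if not train_idx:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    base_cfg = partition_model.config
    if base_cfg.n_tasks != ds.n_tasks or base_cfg.task_type != ds.task_type \
            or base_cfg.use_attention == cfg.ablation.no_attention:
        from dataclasses import replace
        base_cfg = replace(base_cfg, n_tasks=max(ds.n_tasks, 1),
                           task_type=ds.task_type,
                           use_attention=not cfg.ablation.no_attention)
        partition_model.config = base_cfg
    model = PropertyModel(base_cfg, rng, partition_model=partition_model)
    opt = Adam(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    gamma_t = (_negative_proportion(ds, train_idx)
               if ds.task_type == "classification" else None)
    y_all, m_all = ds.label_matrix()

    maximize = ds.task_type == "classification"
    best = -np.inf if maximize else np.inf
    best_params = None
    best_epoch = -1
    epochs_since = 0
    log_f = open(log_path, "w") if log_path else None
    history = []
    try:
        for epoch in range(cfg.finetune_epochs):
            opt.lr = cosine_lr(epoch, cfg.finetune_epochs, cfg.learning_rate,
                               cfg.lr_floor)
            epoch_loss = 0.0
            n_batches = 0
            for bidx in _batches(len(train_idx), cfg.batch_size, rng):
                idx = [train_idx[i] for i in bidx]
                graphs = [ds.graphs[i] for i in idx]
                preds, aux = model.forward_batch(graphs, training=True,
                                                 dropout_rng=rng)
                y_b, m_b = y_all[idx], m_all[idx]
                if ds.task_type == "classification":
                    pos = preds[:, :, 1]
                    L_sup = masked_focal_loss(pos, y_b, m_b,
                                              alpha_t=cfg.alpha_t,
                                              gamma_t=gamma_t)
                else:
                    L_sup = masked_mse(preds, y_b, m_b)
                include_clu = (not cfg.ablation.no_clustering
                               and model.bank.all_initialized)
                L_ss, _ = self_supervised_loss(
                    graphs, aux["S_list"], aux["Z_list"], model.bank, weights,
                    include_connectivity=not cfg.ablation.no_connectivity,
                    include_clustering=include_clu)
                total = supervised_total_loss(L_sup, L_ss, cfg.lambda_sup)
                _check_finite(float(total.data), f"fine-tuning epoch {epoch}")
                opt.zero_grad()
                total.backward()
                clip_grad_norm(model.params, cfg.grad_clip)
                opt.step()
                if not cfg.freeze_prototypes and not cfg.ablation.no_clustering:
                    update_prototypes(model.bank, aux["Z_list"])
                epoch_loss += float(total.data)
                n_batches += 1

            # validation for early stopping; degenerate single-class
            # validation splits fall back to the training loss
            val = None
            if valid_idx:
                val_pred = model.predict_dataset([ds.graphs[i] for i in valid_idx],
                                                 cfg.batch_size)
                try:
                    val = evaluate(val_pred, y_all[valid_idx], ds.task_type,
                                   m_all[valid_idx])["value"]
                except ValueError:
                    val = None
            if val is None:
                val = -epoch_loss / max(n_batches, 1) if maximize else \
                    epoch_loss / max(n_batches, 1)
            improved = val > best if maximize else val < best
            if improved:
                best = val
                best_epoch = epoch
                best_params = {k: p.data.copy() for k, p in model.params.items()}
                best_bank = (model.bank.P.copy(), model.bank.initialized.copy())
                epochs_since = 0
            else:
                epochs_since += 1
            rec = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                   "valid_metric": float(val)}
            history.append(rec)
            if log_f:
                log_f.write(json.dumps(rec) + "\n")
            if epochs_since >= cfg.patience:
                break
    finally:
        if log_f:
            log_f.close()

    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
        model.bank.P, model.bank.initialized = best_bank

    report = {"best_epoch": best_epoch, "valid_metric": float(best),
              "history": history}
    if test_idx:
        test_pred = model.predict_dataset([ds.graphs[i] for i in test_idx],
                                          cfg.batch_size)
        try:
            report["test"] = evaluate(test_pred, y_all[test_idx], ds.task_type,
                                      m_all[test_idx])
        except ValueError as err:
            report["test"] = {"metric": None, "value": float("nan"),
                              "warning": str(err)}
    return model, report


def aggregate_metric(values) -> dict:
    """Mean ± standard deviation across independent runs (seed study)."""
    arr = np.asarray(list(values), dtype=np.float64)
    return {"mean": float(arr.mean()), "std": float(arr.std(ddof=0)),
            "n_runs": int(arr.size)}
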