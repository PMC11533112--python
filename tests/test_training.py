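"""Training loops: progress, determinism, checkpoints, evaluation, schedules."""

import numpy as np
import pytest

from protofrag.autodiff import no_grad
from protofrag.model import (ModelConfig, PartitionModel, PropertyModel,
                             load_checkpoint, save_checkpoint)
from protofrag.nn import cosine_lr
from protofrag.training import (AblationFlags, TrainConfig, aggregate_metric,
                                evaluate, finetune, pretrain)
from protofrag.io import SplitSpec, split_dataset


def _quick_train_cfg(**kw):
    base = dict(pretrain_epochs=8, finetune_epochs=8, patience=5,
                batch_size=16, learning_rate=5e-3, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestPretrain:
    def test_loss_decreases_on_planted_motifs(self, small_dataset, tiny_model_config):
        cfg = _quick_train_cfg(pretrain_epochs=12)
        _, hist = pretrain(small_dataset, cfg, tiny_model_config)
        first = np.mean([h["L_ss"] for h in hist[:3]])
        last = np.mean([h["L_ss"] for h in hist[-3:]])
        assert last < first

    def test_same_seed_identical_first_epoch_loss(self, small_dataset,
                                                  tiny_model_config):
        cfg = _quick_train_cfg(pretrain_epochs=1)
        _, h1 = pretrain(small_dataset, cfg, tiny_model_config)
        _, h2 = pretrain(small_dataset, cfg, tiny_model_config)
        assert h1[0]["L_ss"] == h2[0]["L_ss"]

    def test_loss_log_written_as_json_lines(self, small_dataset,
                                            tiny_model_config, tmp_path):
        import json
        log = tmp_path / "pre.jsonl"
        cfg = _quick_train_cfg(pretrain_epochs=2)
        pretrain(small_dataset, cfg, tiny_model_config, log_path=log)
        records = [json.loads(l) for l in log.read_text().splitlines()]
        assert len(records) == 2
        assert {"epoch", "L_p", "L_d", "modularity", "L_o", "L_ss"} <= set(records[0])

    def test_empty_dataset_rejected(self, tiny_model_config):
        from protofrag.graphs import LabeledDataset
        with pytest.raises(ValueError):
            pretrain(LabeledDataset([], [], "classification"),
                     _quick_train_cfg(), tiny_model_config)


class TestCheckpoint:
    def test_partition_round_trip_identical_outputs(self, small_dataset,
                                                    tiny_model_config, tmp_path):
        cfg = _quick_train_cfg(pretrain_epochs=2)
        model, _ = pretrain(small_dataset, cfg, tiny_model_config)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        loaded, _ = load_checkpoint(path, expect_kind="partition")
        graphs = small_dataset.graphs[:4]
        with no_grad():
            _, H1, S1, _ = model.forward_batch(graphs)
            _, H2, S2, _ = loaded.forward_batch(graphs)
        assert np.array_equal(H1.data, H2.data)  # bit-stable round trip
        assert np.array_equal(S1[0].values, S2[0].values)

    def test_wrong_kind_rejected(self, small_dataset, tiny_model_config, tmp_path):
        from protofrag.encoder import ConfigError
        model, _ = pretrain(small_dataset, _quick_train_cfg(pretrain_epochs=1),
                            tiny_model_config)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        with pytest.raises(ConfigError):
            load_checkpoint(path, expect_kind="property")


class TestFinetune:
    def test_learns_separable_motif_presence_task(self, small_dataset,
                                                  tiny_model_config):
        model, _ = pretrain(small_dataset, _quick_train_cfg(pretrain_epochs=5),
                            tiny_model_config)
        splits = split_dataset(small_dataset, SplitSpec(seed=0))
        fmodel, report = finetune(model, small_dataset, splits,
                                  _quick_train_cfg(finetune_epochs=25,
                                                   learning_rate=3e-3))
        assert report["test"]["metric"] == "roc_auc"
        assert report["test"]["value"] >= 0.7  # separable by construction

    def test_no_attention_ablation_shrinks_representation(self, small_dataset,
                                                          tiny_model_config):
        model, _ = pretrain(small_dataset, _quick_train_cfg(pretrain_epochs=1),
                            tiny_model_config)
        splits = split_dataset(small_dataset, SplitSpec(seed=0))
        cfg = _quick_train_cfg(finetune_epochs=1,
                               ablation=AblationFlags(no_attention=True))
        fmodel, _ = finetune(model, small_dataset, splits, cfg)
        d = tiny_model_config.hidden_dim
        assert fmodel.rep_dim == d
        cfg2 = _quick_train_cfg(finetune_epochs=1)
        model2, _ = pretrain(small_dataset, _quick_train_cfg(pretrain_epochs=1),
                             tiny_model_config)
        fmodel2, _ = finetune(model2, small_dataset, splits, cfg2)
        M = tiny_model_config.cross_attention_heads
        assert fmodel2.rep_dim == d + M * d

    def test_regression_on_linear_motif_counts(self, tiny_model_config):
        from protofrag.synthetic import generate_dataset, planted_to_dataset
        planted = generate_dataset(n_graphs=60, n_motif_classes=4,
                                   label_rule="count_linear", seed=5)
        ds = planted_to_dataset(planted, "regression")
        mc = ModelConfig(node_dim=tiny_model_config.node_dim,
                         edge_dim=tiny_model_config.edge_dim,
                         hidden_dim=16, num_layers=2, n_classes=4,
                         dropout=0.0, n_tasks=1, task_type="regression")
        model, _ = pretrain(ds, _quick_train_cfg(pretrain_epochs=4), mc)
        splits = split_dataset(ds, SplitSpec(seed=0))
        _, report = finetune(model, ds, splits,
                             _quick_train_cfg(finetune_epochs=40,
                                              learning_rate=3e-3))
        y = np.array([p.label for p in planted])
        assert report["test"]["metric"] == "rmse"
        assert report["test"]["value"] < np.std(y)  # beats predicting the mean


class TestEvaluate:
    def test_perfect_ranking_auc_one(self):
        preds = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1.0, 1.0, 0.0, 0.0])
        out = evaluate(preds, labels, "classification")
        assert out["value"] == 1.0

    def test_perfect_regression_rmse_zero(self):
        y = np.array([1.0, -2.0, 0.5])
        assert evaluate(y, y, "regression")["value"] == 0.0

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(0)
        n = 10000
        labels = (rng.random(n) < 0.5).astype(float)
        preds = rng.random(n)
        out = evaluate(preds, labels, "classification")
        assert abs(out["value"] - 0.5) < 0.02

    def test_single_class_task_excluded(self):
        preds = np.array([[0.2, 0.9], [0.8, 0.1]])
        labels = np.array([[1.0, 1.0], [1.0, 0.0]])  # task 0 has one class
        out = evaluate(preds, labels, "classification")
        assert out["n_tasks_scored"] == 1

    def test_all_single_class_raises(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                     "classification")


class TestSchedulesAndAggregation:
    def test_cosine_peak_at_zero_then_monotone_to_floor(self):
        lrs = [cosine_lr(e, 50, 1e-3, 1e-5) for e in range(50)]
        assert lrs[0] == 1e-3
        assert np.isclose(lrs[-1], 1e-5)
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_early_stopping_restores_best_validation_model(self, small_dataset,
                                                           tiny_model_config):
        model, _ = pretrain(small_dataset, _quick_train_cfg(pretrain_epochs=2),
                            tiny_model_config)
        splits = split_dataset(small_dataset, SplitSpec(seed=1))
        fmodel, report = finetune(model, small_dataset, splits,
                                  _quick_train_cfg(finetune_epochs=12, patience=3))
        best = max(h["valid_metric"] for h in report["history"])
        assert np.isclose(report["valid_metric"], best)

    def test_five_seed_aggregation(self):
        out = aggregate_metric([0.8, 0.9, 0.85, 0.95, 0.9])
        assert out["n_runs"] == 5
        assert np.isclose(out["mean"], 0.88)
        assert out["std"] >= 0
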