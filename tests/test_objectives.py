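"""Self-supervised losses: modularity, orthogonality, prototypes, contrastive."""

import numpy as np
import pytest

from protofrag.autodiff import Tensor
from protofrag.graphs import MolecularGraph
from protofrag.objectives import (LossWeights, PrototypeBank,
                                  PrototypeStateError, compactness_loss,
                                  cosine_similarity, modularity,
                                  orthogonality_loss,
                                  prototype_contrastive_loss,
                                  self_supervised_loss, update_prototypes)
from protofrag.partitioner import (AssignmentMatrix, SubstructureEmbeddings,
                                   pool_substructures)

from conftest import random_graph


def hard_S(labels, K):
    S = np.zeros((len(labels), K))
    S[np.arange(len(labels)), labels] = 1.0
    return AssignmentMatrix(S=Tensor(S), tau1=1.0)


def brute_force_modularity(S: np.ndarray, A: np.ndarray) -> float:
    """Explicit double sum over node pairs (independent oracle)."""
    d = A.sum(axis=1)
    m = A.sum() / 2.0
    total = 0.0
    n, K = S.shape
    for i in range(n):
        for j in range(n):
            for c in range(K):
                total += (A[i, j] - d[i] * d[j] / (2 * m)) * S[i, c] * S[j, c]
    return total / (2 * m)


def graph_from_edges(n, edges):
    E = np.array(edges, dtype=np.int64)
    return MolecularGraph(node_features=np.zeros((n, 2)), edge_index=E,
                          edge_features=np.zeros((len(edges), 1)))


class TestModularity:
    def test_single_class_partition_is_zero(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (0, 3)])
        assert abs(float(modularity(hard_S([0] * 4, 3), g).data)) < 1e-12

    def test_two_disjoint_triangles_split_by_component(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        val = float(modularity(hard_S([0, 0, 0, 1, 1, 1], 2), g).data)
        assert np.isclose(val, 0.5, atol=1e-12)

    def test_path_graph_bad_split(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        val = float(modularity(hard_S([0, 0, 1], 2), g).data)
        assert np.isclose(val, -0.125, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_for_soft_assignments(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        g = random_graph(rng, n=n, p_edge=0.4)
        K = int(rng.integers(2, 5))
        S_raw = rng.dirichlet(np.ones(K), size=n)
        S = AssignmentMatrix(S=Tensor(S_raw), tau1=1.0)
        ours = float(modularity(S, g).data)
        oracle = brute_force_modularity(S_raw, g.adjacency)
        assert np.isclose(ours, oracle, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_hard_partitions_match_networkx(self, seed):
        import networkx as nx
        rng = np.random.default_rng(seed + 100)
        n = 8
        g = random_graph(rng, n=n, p_edge=0.35)
        labels = rng.integers(0, 3, size=n)
        labels[:3] = [0, 1, 2]  # all classes nonempty
        G = nx.from_numpy_array(g.adjacency)
        communities = [set(np.flatnonzero(labels == c)) for c in range(3)]
        ref = nx.algorithms.community.modularity(G, communities)
        ours = float(modularity(hard_S(labels.tolist(), 3), g).data)
        assert np.isclose(ours, ref, atol=1e-10)

    def test_edgeless_graph_defined_as_zero_with_warning(self):
        g = MolecularGraph(node_features=np.zeros((2, 2)),
                           edge_index=np.zeros((0, 2)),
                           edge_features=np.zeros((0, 1)))
        with pytest.warns(UserWarning, match="edgeless"):
            assert float(modularity(hard_S([0, 1], 2), g).data) == 0.0


class TestOrthogonality:
    def test_balanced_hard_partition_is_zero(self):
        assert abs(float(orthogonality_loss(hard_S([0, 0, 1, 1], 2)).data)) < 1e-12

    def test_single_class_collapse(self):
        val = float(orthogonality_loss(hard_S([0, 0, 0, 0], 2)).data)
        assert np.isclose(val, np.sqrt(2) - 1, atol=1e-12)

    def test_three_one_imbalance(self):
        val = float(orthogonality_loss(hard_S([0, 0, 0, 1], 2)).data)
        assert np.isclose(val, (np.sqrt(2) / 4) * np.sqrt(10) - 1, atol=1e-12)
        assert np.isclose(val, 0.1180, atol=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_nonnegative_and_zero_iff_balanced(self, seed):
        rng = np.random.default_rng(seed)
        n, K = int(rng.integers(2, 12)), int(rng.integers(2, 5))
        S_raw = rng.dirichlet(np.ones(K), size=n)
        val = float(orthogonality_loss(
            AssignmentMatrix(S=Tensor(S_raw), tau1=1.0)).data)
        assert val >= -1e-9
        masses = S_raw.sum(axis=0)
        if np.allclose(masses, n / K, atol=1e-12):
            assert abs(val) < 1e-9


class TestCosine:
    def test_self_similarity_one(self):
        u = np.array([1.0, 2.0, -3.0])
        assert np.isclose(float(cosine_similarity(u, u).data), 1.0)

    def test_antiparallel_minus_one(self):
        u = np.array([1.0, 2.0])
        assert np.isclose(float(cosine_similarity(u, -u).data), -1.0)

    def test_orthogonal_zero(self):
        assert np.isclose(
            float(cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 2.0])).data),
            0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity(np.zeros(3), np.ones(3))


def _emb(values, present=None):
    values = np.asarray(values, dtype=float)
    present = (np.ones(values.shape[0], bool) if present is None
               else np.asarray(present, bool))
    return SubstructureEmbeddings(Z=Tensor(values * present[:, None]),
                                  presence_mask=present)


class TestPrototypeUpdates:
    def test_momentum_one_keeps_prototypes(self):
        bank = PrototypeBank(2, 3, momentum=1.0,
                             P=np.arange(6.).reshape(2, 3),
                             initialized=np.ones(2, bool))
        before = bank.P.copy()
        update_prototypes(bank, [_emb(np.ones((2, 3)))])
        assert np.array_equal(bank.P, before)

    def test_momentum_zero_takes_batch_mean(self):
        bank = PrototypeBank(2, 2, momentum=0.0, P=np.ones((2, 2)),
                             initialized=np.ones(2, bool))
        update_prototypes(bank, [_emb([[2.0, 0.0], [0.0, 4.0]]),
                                 _emb([[4.0, 0.0], [0.0, 8.0]])])
        assert np.allclose(bank.P, [[3.0, 0.0], [0.0, 6.0]])

    def test_intermediate_momentum_convex_combination(self):
        bank = PrototypeBank(1, 2, momentum=0.5, P=np.array([[1.0, 0.0]]),
                             initialized=np.ones(1, bool))
        update_prototypes(bank, [_emb([[0.0, 1.0]])])
        assert np.allclose(bank.P, [[0.5, 0.5]])

    def test_first_touch_sets_prototype_directly(self):
        bank = PrototypeBank(2, 2, momentum=0.9)
        update_prototypes(bank, [_emb([[3.0, 1.0], [0.0, 0.0]],
                                      present=[True, False])])
        assert bank.initialized.tolist() == [True, False]
        assert np.allclose(bank.P[0], [3.0, 1.0])

    def test_absent_classes_untouched(self):
        bank = PrototypeBank(2, 2, momentum=0.0, P=np.full((2, 2), 7.0),
                             initialized=np.ones(2, bool))
        update_prototypes(bank, [_emb([[1.0, 1.0], [0.0, 0.0]],
                                      present=[True, False])])
        assert np.allclose(bank.P[1], 7.0)


def _aligned_bank(K, d=None):
    """Prototypes = coordinate axes, so instances on axis c have s=1 to
    their prototype and 0 to all others."""
    d = d or K
    return PrototypeBank(K, d, P=np.eye(K, d), initialized=np.ones(K, bool))


class TestContrastive:
    def test_single_class_no_negatives_zero_loss(self):
        bank = _aligned_bank(1, 3)
        val = float(prototype_contrastive_loss(
            [_emb([[2.0, 0.0, 0.0]])], bank, tau2=1.0).data)
        assert abs(val) < 1e-12

    @pytest.mark.parametrize("K", [2, 3, 5])
    def test_aligned_orthogonal_closed_form(self, K):
        bank = _aligned_bank(K)
        Z = _emb(np.eye(K) * 3.0)  # instance c sits on axis c
        val = float(prototype_contrastive_loss([Z], bank, tau2=1.0).data)
        expect = -np.log(np.e / (np.e + K - 1))
        assert np.isclose(val, expect, atol=1e-9)

    def test_all_equal_similarities_log_k(self):
        K = 4
        bank = PrototypeBank(K, K, P=np.tile([1.0, 0, 0, 0], (K, 1)),
                             initialized=np.ones(K, bool))
        Z = _emb(np.tile([2.0, 0, 0, 0], (K, 1)))
        val = float(prototype_contrastive_loss([Z], bank, tau2=1.0).data)
        assert np.isclose(val, np.log(K), atol=1e-9)

    def test_uninitialized_prototype_raises_state_error(self):
        bank = PrototypeBank(2, 2)
        with pytest.raises(PrototypeStateError):
            prototype_contrastive_loss([_emb(np.eye(2))], bank, tau2=1.0)

    def test_loss_decreases_as_positive_similarity_grows(self):
        bank = _aligned_bank(3)
        losses = []
        for pull in (0.0, 0.5, 2.0):
            Z = np.eye(3) + 0.1
            Z[0] = [1.0 + pull, 0.1, 0.1]
            losses.append(float(prototype_contrastive_loss(
                [_emb(Z[:1], present=[True, False, False])], bank, 0.5).data))
        assert losses[0] > losses[1] > losses[2]


class TestCompactness:
    def test_parallel_zero(self):
        bank = _aligned_bank(2)
        Z = _emb([[5.0, 0.0], [0.0, 0.0]], present=[True, False])
        assert abs(float(compactness_loss([Z], bank).data)) < 1e-12

    def test_orthogonal_one(self):
        bank = _aligned_bank(2)
        Z = _emb([[0.0, 3.0], [0.0, 0.0]], present=[True, False])
        assert np.isclose(float(compactness_loss([Z], bank).data), 1.0)

    def test_antiparallel_four(self):
        bank = _aligned_bank(2)
        Z = _emb([[-2.0, 0.0], [0.0, 0.0]], present=[True, False])
        assert np.isclose(float(compactness_loss([Z], bank).data), 4.0)


class TestTotalLoss:
    def _setup(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, n=6, p_edge=0.5)
        S_raw = rng.dirichlet(np.ones(3), size=6)
        S = AssignmentMatrix(S=Tensor(S_raw), tau1=1.0)
        Z = pool_substructures(S, Tensor(rng.normal(size=(6, 4))))
        bank = PrototypeBank(3, 4, P=rng.normal(size=(3, 4)),
                             initialized=np.ones(3, bool))
        return g, S, Z, bank

    def test_component_arithmetic(self):
        # with component values (L_p, L_d, -mod, L_o) the total must be
        # gamma*(L_p + beta*L_d) + (1-gamma)*(-mod + alpha*L_o)
        g, S, Z, bank = self._setup()
        w = LossWeights(alpha=1.0, beta=1.0, gamma=0.5, tau2=0.5)
        total, bd = self_supervised_loss([g], [S], [Z], bank, w)
        expect = (w.gamma * (bd["L_p"] + w.beta * bd["L_d"])
                  + (1 - w.gamma) * (-bd["modularity"] + w.alpha * bd["L_o"]))
        assert np.isclose(float(total.data), expect, atol=1e-12)

    def test_gamma_one_clusters_only(self):
        g, S, Z, bank = self._setup()
        total, bd = self_supervised_loss([g], [S], [Z], bank,
                                         LossWeights(gamma=1.0, tau2=0.5))
        assert np.isclose(float(total.data), bd["L_clu"], atol=1e-12)

    def test_gamma_zero_connectivity_only(self):
        g, S, Z, bank = self._setup()
        total, bd = self_supervised_loss([g], [S], [Z], bank,
                                         LossWeights(gamma=0.0, tau2=0.5))
        assert np.isclose(float(total.data), bd["L_con"], atol=1e-12)

    def test_orthogonality_scope_batch_vs_graph(self):
        rng = np.random.default_rng(1)
        graphs, S_list, Z_list = [], [], []
        for _ in range(3):
            g = random_graph(rng, n=5, p_edge=0.5)
            S = AssignmentMatrix(S=Tensor(rng.dirichlet(np.ones(2), size=5)),
                                 tau1=1.0)
            graphs.append(g)
            S_list.append(S)
            Z_list.append(pool_substructures(S, Tensor(rng.normal(size=(5, 4)))))
        bank = PrototypeBank(2, 4, P=rng.normal(size=(2, 4)),
                             initialized=np.ones(2, bool))
        w = LossWeights(tau2=0.5)
        _, bd_batch = self_supervised_loss(graphs, S_list, Z_list, bank, w,
                                           orthogonality="batch")
        _, bd_graph = self_supervised_loss(graphs, S_list, Z_list, bank, w,
                                           orthogonality="graph")
        S_cat = np.concatenate([S.values for S in S_list])
        expect_batch = float(orthogonality_loss(
            AssignmentMatrix(S=Tensor(S_cat), tau1=1.0)).data)
        expect_graph = np.mean([float(orthogonality_loss(S).data)
                                for S in S_list])
        assert np.isclose(bd_batch["L_o"], expect_batch, atol=1e-12)
        assert np.isclose(bd_graph["L_o"], expect_graph, atol=1e-12)

    def test_gradients_flow_from_every_component(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, n=6, p_edge=0.5)
        for gamma in (0.0, 1.0):
            logits = Tensor(rng.normal(size=(6, 3)), requires_grad=True)
            H = Tensor(rng.normal(size=(6, 4)), requires_grad=True)
            S = AssignmentMatrix(S=logits.softmax(axis=1), tau1=1.0)
            Z = pool_substructures(S, H)
            bank = PrototypeBank(3, 4, P=rng.normal(size=(3, 4)),
                                 initialized=np.ones(3, bool))
            total, _ = self_supervised_loss([g], [S], [Z], bank,
                                            LossWeights(gamma=gamma, tau2=0.5))
            total.backward()
            assert logits.grad is not None and np.linalg.norm(logits.grad) > 0
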