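"""Classifier families: fitting behaviour, determinism, gradient surfaces."""

import numpy as np
import pytest

from gxplain.models import (
    balanced_accuracy,
    build_correlation_graph,
    coarsen_graph,
    train_gbt,
    train_gnn,
    train_logistic,
    train_mlp,
)
from gxplain.models.graph import CorrelationGraph
from scipy import sparse


def two_gene_toy(n=20, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (n, 2))
    y = np.where(x[:, 0] > 0, 2, 1)
    return x, y


class TestLogistic:
    def test_separable_toy_weights_and_accuracy(self):
        x, y = two_gene_toy()
        m = train_logistic(x, y, ["g1", "g2"], penalty="l2",
                           regularization_strength=0.01, seed=0)
        assert abs(m.weights[0, 0]) > 5 * abs(m.weights[0, 1])
        assert balanced_accuracy(m.predict(x), y) == 1.0

    def test_l1_strong_regularization_sparsifies(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (80, 100))
        y = np.where(x[:, 0] + 0.1 * rng.normal(size=80) > 0, 2, 1)
        m = train_logistic(x, y, [f"g{i}" for i in range(100)], penalty="l1",
                           regularization_strength=5.0, seed=0)
        assert np.mean(m.weights == 0) >= 0.9

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (200, 10))
        y = rng.permutation(np.repeat([1, 2], 100))
        m = train_logistic(x, y, [f"g{i}" for i in range(10)], penalty="l2", seed=0)
        rng2 = np.random.default_rng(3)
        x_new = rng2.normal(0, 1, (200, 10))
        y_new = np.repeat([1, 2], 100)
        assert abs(balanced_accuracy(m.predict(x_new), y_new) - 0.5) < 0.15

    def test_probabilities_normalized_multiclass(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (90, 5))
        y = np.repeat([1, 2, 3], 30)
        x[y == 2, 0] += 3
        x[y == 3, 1] += 3
        m = train_logistic(x, y, [f"g{i}" for i in range(5)], penalty="l2", seed=0)
        p = m.predict_proba(x)
        assert p.shape == (90, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()


class TestMLP:
    def test_xor_needs_hidden_layer(self):
        rng = np.random.default_rng(0)
        x = rng.choice([-1.0, 1.0], size=(200, 2)) + rng.normal(0, 0.1, (200, 2))
        y = np.where(x[:, 0] * x[:, 1] > 0, 1, 2)
        m = train_mlp(x, y, ["g1", "g2"], hidden_sizes=(8,), epochs=50, seed=0)
        assert balanced_accuracy(m.predict(x), y) >= 0.95

    def test_zero_hidden_width_rejected(self):
        x, y = two_gene_toy()
        with pytest.raises(ValueError):
            train_mlp(x, y, ["g1", "g2"], hidden_sizes=(0,))
        with pytest.raises(ValueError):
            train_mlp(x, y, ["g1", "g2"], hidden_sizes=(4, 4, 4))

    def test_same_seed_identical_predictions(self):
        x, y = two_gene_toy(n=60)
        a = train_mlp(x, y, ["g1", "g2"], hidden_sizes=(8,), epochs=5, seed=9)
        b = train_mlp(x, y, ["g1", "g2"], hidden_sizes=(8,), epochs=5, seed=9)
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))


class TestCorrelationGraph:
    def test_duplicate_genes_edge_kept_first(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        x = np.column_stack([a, a, rng.normal(0, 1, 50)])
        g = build_correlation_graph(x, edge_budget=1)
        assert g.adjacency[0, 1] == pytest.approx(1.0)
        assert g.adjacency.nnz == 2  # symmetric storage of one edge

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            build_correlation_graph(np.ones((5, 3)), edge_budget=0)

    def test_top_edges_match_brute_force(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (40, 10))
        budget = 5
        g = build_correlation_graph(x, budget)
        corr = np.abs(np.corrcoef(x, rowvar=False))
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        expected = set(sorted(pairs, key=lambda p: -corr[p])[:budget])
        kept = set(zip(*sparse.triu(g.adjacency, k=1).nonzero()))
        assert kept == expected

    def test_constant_column_treated_as_uncorrelated(self):
        x = np.column_stack([np.ones(30), np.arange(30.0), np.arange(30.0) * 2])
        g = build_correlation_graph(x, edge_budget=1)
        assert g.adjacency[0, 1] == 0
        assert g.adjacency[1, 2] == pytest.approx(1.0)


class TestCoarsening:
    @staticmethod
    def path_graph():
        adj = sparse.csr_matrix(np.array([[0, 3, 0], [3, 0, 1], [0, 1, 0]], dtype=float))
        return CorrelationGraph(adjacency=adj, edge_budget=2)

    def test_heavy_edge_merged_first(self):
        coarse = coarsen_graph(self.path_graph())
        assert coarse.n_nodes == 2
        cluster = coarse.coarsening_maps[-1]
        assert cluster[0] == cluster[1] != cluster[2]
        assert coarse.adjacency.toarray().max() == pytest.approx(1.0)

    def test_edgeless_graph_all_singletons(self):
        g = CorrelationGraph(adjacency=sparse.csr_matrix((4, 4)), edge_budget=1)
        coarse = coarsen_graph(g)
        assert coarse.n_nodes == 4

    def test_matching_bound_on_node_count(self, processed):
        g = build_correlation_graph(processed.x_train, 100)
        coarse = coarsen_graph(g)
        assert coarse.n_nodes >= int(np.ceil(g.n_nodes / 2))


class TestGNN:
    def test_normalized_propagation_hand_example(self):
        adj = sparse.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        g = CorrelationGraph(adjacency=adj, edge_budget=1)
        s = g.normalized_propagator().toarray()
        np.testing.assert_allclose(s, [[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(s @ np.array([1.0, 0.0]), [0.5, 0.5])

    def test_edgeless_graph_identity_propagator(self):
        g = CorrelationGraph(adjacency=sparse.csr_matrix((3, 3)), edge_budget=1)
        np.testing.assert_allclose(g.normalized_propagator().toarray(), np.eye(3))

    def test_same_seed_identical_predictions(self, processed):
        graph = build_correlation_graph(processed.x_train, 50)
        kw = dict(epochs=3, seed=4)
        a = train_gnn(processed.x_train, processed.y_train, processed.kept_gene_names, graph, **kw)
        b = train_gnn(processed.x_train, processed.y_train, processed.kept_gene_names, graph, **kw)
        np.testing.assert_array_equal(
            a.predict_proba(processed.x_test), b.predict_proba(processed.x_test)
        )

    def test_dimension_mismatch_rejected(self, processed):
        graph = build_correlation_graph(processed.x_train[:, :10], 5)
        with pytest.raises(ValueError, match="nodes"):
            train_gnn(processed.x_train, processed.y_train, processed.kept_gene_names, graph)


class TestGBT:
    def test_single_informative_gene_gets_all_gain(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (100, 8))
        x[:, 3] = rng.choice([-1.0, 1.0], 100)
        y = np.where(x[:, 3] > 0, 2, 1)
        m = train_gbt(x, y, [f"g{i}" for i in range(8)], n_estimators=3, max_depth=1)
        gains = m.feature_importances
        assert np.count_nonzero(gains) == 1 and gains[3] > 0

    def test_two_runs_identical_gains(self, processed):
        a = train_gbt(processed.x_train, processed.y_train, processed.kept_gene_names)
        b = train_gbt(processed.x_train, processed.y_train, processed.kept_gene_names)
        np.testing.assert_array_equal(a.feature_importances, b.feature_importances)

    def test_pure_noise_near_chance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (200, 5))
        y = rng.permutation(np.repeat([1, 2], 100))
        m = train_gbt(x, y, [f"g{i}" for i in range(5)], n_estimators=1, max_depth=1)
        assert abs(balanced_accuracy(m.predict(x), y) - 0.5) < 0.15


class TestBalancedAccuracy:
    def test_perfect_and_averaged_recalls(self):
        assert balanced_accuracy([1, 2, 1], [1, 2, 1]) == 1.0
        # class 1 recall 1.0, class 2 recall 0.5
        assert balanced_accuracy([1, 1, 2, 1], [1, 1, 2, 2]) == 0.75

    def test_matches_enumeration_on_three_classes(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(1, 4, 60)
        truth[:3] = [1, 2, 3]
        pred = rng.integers(1, 4, 60)
        expected = np.mean([
            np.mean(pred[truth == c] == c) for c in (1, 2, 3)
        ])
        assert balanced_accuracy(pred, truth) == pytest.approx(expected)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            balanced_accuracy(np.array([1, 2]), np.array([2, 2]))


@pytest.mark.parametrize("family", ["lr", "mlp", "gnn"])
def test_input_gradients_match_finite_differences(family, processed, lr_model, mlp_model, gnn_model):
    model = {"lr": lr_model, "mlp": mlp_model, "gnn": gnn_model}[family]
    rng = np.random.default_rng(12)
    x = processed.x_train
    eps = 1e-5
    for _ in range(5):
        i = rng.integers(0, x.shape[0])
        j = rng.integers(0, x.shape[1])
        c = int(rng.integers(1, processed.n_classes + 1))
        xp, xm = x[i].copy(), x[i].copy()
        xp[j] += eps
        xm[j] -= eps
        fd = (model.predict_proba(xp[None])[0, c - 1] - model.predict_proba(xm[None])[0, c - 1]) / (2 * eps)
        an = model.input_gradient(x[i][None], c)[0, j]
        assert an == pytest.approx(fd, rel=1e-4, abs=1e-9)
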