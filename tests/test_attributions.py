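"""Integrated gradients, score aggregation, and prediction-gap curves."""

import numpy as np
import pytest

from gxplain.attributions import (
    aggregate_class_scores,
    aggregate_global,
    compute_ig_ranking,
    default_baseline,
    integrated_gradients,
    prediction_gap,
)
from gxplain.models import train_gbt, train_logistic
from gxplain.models.linear import LogisticModel
from gxplain.rankers import GeneRanking


def linear_model(w, b=0.0):
    w = np.atleast_2d(np.asarray(w, dtype=float))
    return LogisticModel(weights=w, intercepts=np.atleast_1d(b), penalty="l2",
                         gene_names=[f"g{i}" for i in range(w.shape[1])],
                         n_classes=2, seed=0)


def ig_linear_closed_form(w, b, x, x_prime, target_class=2):
    """For a linear logit z = w.x + b, the path integral has the closed form
    phi_g = (x_g - x'_g) w_g (sigma(z1) - sigma(z0)) / (z1 - z0)."""
    sigma = lambda z: 1.0 / (1.0 + np.exp(-z))
    z1, z0 = float(w @ x + b), float(w @ x_prime + b)
    factor = (sigma(z1) - sigma(z0)) / (z1 - z0) if z1 != z0 else sigma(z1) * (1 - sigma(z1))
    phi = (x - x_prime) * w * factor
    return phi if target_class == 2 else -phi


class TestIntegratedGradients:
    def test_baseline_equals_sample_gives_zero(self, lr_model, processed):
        x = processed.x_train[0]
        scores, residual = integrated_gradients(lr_model, x, x, 2, n_steps=32)
        np.testing.assert_array_equal(scores, 0.0)
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_worked_binary_example(self):
        m = linear_model([1.0, 0.0])
        x, x0 = np.array([2.0, 0.0]), np.zeros(2)
        scores, _ = integrated_gradients(m, x, x0, 2, n_steps=1024)
        sigma = lambda z: 1.0 / (1.0 + np.exp(-z))
        assert scores[0] == pytest.approx(sigma(2) - sigma(0), abs=1e-6)
        assert scores[0] == pytest.approx(0.3808, abs=1e-4)
        assert scores[1] == 0.0

    def test_matches_closed_form_on_random_linear_models(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            w = rng.normal(0, 1, 6)
            b = rng.normal()
            x = rng.normal(0, 2, 6)
            x0 = rng.normal(0, 2, 6)
            m = linear_model(w, b)
            scores, _ = integrated_gradients(m, x, x0, 2, n_steps=1024)
            np.testing.assert_allclose(scores, ig_linear_closed_form(w, b, x, x0), atol=1e-6)

    @pytest.mark.parametrize("family", ["mlp", "gnn"])
    def test_completeness_on_neural_models(self, family, mlp_model, gnn_model, processed):
        model = {"mlp": mlp_model, "gnn": gnn_model}[family]
        x = processed.x_train[3]
        baseline = default_baseline(processed)
        _, residual = integrated_gradients(model, x, baseline, 2, n_steps=512)
        assert residual < 1e-3

    def test_residual_shrinks_as_steps_double(self, mlp_model, processed):
        x = processed.x_train[5]
        baseline = default_baseline(processed)
        residuals = [integrated_gradients(mlp_model, x, baseline, 2, n_steps=n)[1]
                     for n in (16, 32, 64, 128, 256, 512)]
        assert residuals[-1] <= residuals[0]
        # monotone decrease until the float-accumulation noise floor
        for a, b in zip(residuals, residuals[1:]):
            assert b <= a + 1e-9 or b < 1e-6

    def test_tree_model_rejected(self, processed):
        m = train_gbt(processed.x_train, processed.y_train, processed.kept_gene_names,
                      n_estimators=1)
        with pytest.raises(TypeError, match="gradient"):
            integrated_gradients(m, processed.x_train[0], processed.x_train[1], 2)


class TestAggregation:
    def test_single_sample_l2_normalization(self):
        out = aggregate_class_scores(np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(out, [0.6, 0.8])

    def test_identical_samples_idempotent(self):
        one = aggregate_class_scores(np.array([[3.0, 4.0]]))
        two = aggregate_class_scores(np.array([[3.0, 4.0], [3.0, 4.0]]))
        np.testing.assert_allclose(one, two)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(1)
        local = rng.normal(0, 2, (5, 7))
        expected = np.zeros(7)
        for n in range(5):
            expected += np.abs(local[n]) / np.linalg.norm(local[n])
        expected /= 5
        np.testing.assert_allclose(aggregate_class_scores(local), expected, atol=1e-12)

    def test_unit_norm_of_each_normalized_vector(self):
        rng = np.random.default_rng(2)
        local = rng.normal(0, 1, (4, 9))
        normalized = np.abs(local) / np.linalg.norm(local, axis=1, keepdims=True)
        np.testing.assert_allclose(np.linalg.norm(normalized, axis=1), 1.0, atol=1e-12)

    def test_zero_vector_excluded_with_warning(self):
        local = np.array([[0.0, 0.0], [3.0, 4.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            out = aggregate_class_scores(local)
        np.testing.assert_allclose(out, [0.6, 0.8])

    def test_global_average(self):
        assert aggregate_global([np.array([1.0, 0.0])]).tolist() == [1.0, 0.0]
        np.testing.assert_allclose(
            aggregate_global([np.array([1.0, 0.0]), np.array([0.0, 1.0])]), [0.5, 0.5]
        )
        rng = np.random.default_rng(3)
        vecs = rng.uniform(0, 1, (3, 6))
        np.testing.assert_allclose(aggregate_global(list(vecs)), vecs.mean(axis=0))


class TestPredictionGap:
    def test_hand_worked_two_gene_example(self):
        class TwoStep:
            """f_c(x) = 0.8 unmasked, 0.6 with one gene masked, 0.2 with two."""
            model_family = "toy"
            has_gradient = False

            def predict(self, x):
                return np.array([2] * len(x))

            def predict_proba(self, x):
                ref_count = np.isclose(x, -1.0).sum(axis=1)
                p2 = np.choose(ref_count, [0.8, 0.6, 0.2])
                return np.column_stack([1 - p2, p2])

        ranking = GeneRanking("m", ["a", "b"], np.array([2.0, 1.0]))
        curve = prediction_gap(TwoStep(), np.zeros(2), ranking, "important_first",
                               np.full(2, -1.0), target_class=2)
        assert curve.pg_value == pytest.approx(0.5)
        assert curve.per_fraction_outputs[0] == pytest.approx(0.8)

    def test_constant_model_zero_gap(self):
        class Constant:
            model_family = "toy"
            has_gradient = False

            def predict(self, x):
                return np.array([1] * len(x))

            def predict_proba(self, x):
                return np.tile([0.7, 0.3], (len(x), 1))

        ranking = GeneRanking("m", ["a", "b", "c"], np.array([3.0, 2.0, 1.0]))
        for order in ("important_first", "unimportant_first", "random"):
            curve = prediction_gap(Constant(), np.zeros(3), ranking, order, np.ones(3))
            assert curve.pg_value == 0.0

    def test_reversed_ranking_swaps_pgi_and_pgu(self, lr_model, processed):
        x = processed.x_train[0]
        baseline = default_baseline(processed)
        ranking = GeneRanking("m", processed.kept_gene_names,
                              np.abs(lr_model.weights[0]))
        reversed_ranking = GeneRanking("m", processed.kept_gene_names,
                                       -np.abs(lr_model.weights[0]))
        pgi = prediction_gap(lr_model, x, ranking, "important_first", baseline, 2)
        pgu_rev = prediction_gap(lr_model, x, reversed_ranking, "unimportant_first", baseline, 2)
        assert pgi.pg_value == pytest.approx(pgu_rev.pg_value, abs=1e-9)

    def test_single_informative_gene_pgi_exceeds_pgu(self, single_informative_gene):
        x, y, names = single_informative_gene
        model = linear_model([4.0] + [0.0] * 19)
        ranking = GeneRanking("m", names, np.abs(model.weights[0]))
        sample = x[y == 2][0]
        baseline = x[y == 1].mean(axis=0)
        pgi = prediction_gap(model, sample, ranking, "important_first", baseline, 2)
        pgu = prediction_gap(model, sample, ranking, "unimportant_first", baseline, 2)
        assert pgi.pg_value > pgu.pg_value
        # only the final mask (the informative gene) moves the prediction
        assert pgu.pg_value == pytest.approx(1.0 / 20, abs=0.02)

    def test_zero_confidence_rejected(self):
        class Zero:
            model_family = "toy"
            has_gradient = False

            def predict(self, x):
                return np.array([1] * len(x))

            def predict_proba(self, x):
                return np.tile([1.0, 0.0], (len(x), 1))

        ranking = GeneRanking("m", ["a", "b"], np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="undefined"):
            prediction_gap(Zero(), np.zeros(2), ranking, "important_first",
                           np.zeros(2), target_class=2)


class TestIGRanking:
    def test_planted_gene_tops_global_ranking(self, single_informative_gene):
        x, y, names = single_informative_gene
        top_hits = 0
        for seed in range(10):
            m = train_logistic(x, y, names, penalty="l2", seed=seed)
            from gxplain.preprocess import ProcessedDataset

            p = ProcessedDataset(
                matrix=x, kept_gene_names=names,
                sample_ids=[f"s{i}" for i in range(len(y))], labels=y,
                train_index=np.arange(len(y)), test_index=np.array([], dtype=int),
                standardizer_means=np.zeros(x.shape[1]),
                standardizer_stds=np.ones(x.shape[1]),
            )
            ranking, result = compute_ig_ranking(m, p, n_steps=64, seed=seed)
            if ranking.ranks[0] == 1:
                top_hits += 1
        assert top_hits >= 9
        assert (result.class_scores >= 0).all()
        assert (result.global_scores >= 0).all()
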