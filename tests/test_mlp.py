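"""Classifier network: forward, gradients, training, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from snpclassify import (
    MLPModel,
    TrainConfig,
    evaluate,
    forward,
    init_model,
    input_gradient,
    loss_value,
    train,
)


def zero_model(k_in=3, c=4, hidden=(5,)):
    sizes = (k_in, *hidden, c)
    return MLPModel(
        weights=[np.zeros((a, b)) for a, b in zip(sizes[:-1], sizes[1:])],
        biases=[np.zeros(b) for b in sizes[1:]],
    )


def finite_difference_gradient(model, X, Y, loss, h=1e-6):
    grad = np.zeros_like(X, dtype=float)
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            up = X.copy().astype(float)
            dn = X.copy().astype(float)
            up[i, j] += h
            dn[i, j] -= h
            grad[i, j] = (
                loss_value(model, up, Y, loss) - loss_value(model, dn, Y, loss)
            ) / (2 * h)
    return grad


class TestInit:
    def test_deterministic_given_seed(self):
        a = init_model(10, 3, seed=4)
        b = init_model(10, 3, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_architecture_shapes(self):
        model = init_model(50, 26, seed=0)
        assert [w.shape for w in model.weights] == [(50, 100), (100, 100), (100, 26)]
        assert model.layer_sizes == (50, 100, 100, 26)
        assert all(not b.any() for b in model.biases)

    def test_zero_weight_model_outputs_uniform(self):
        P = forward(zero_model(c=4), np.random.default_rng(0).normal(size=(6, 3)))
        assert np.allclose(P, 0.25)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="2 classes"):
            init_model(5, 1, seed=0)


class TestForward:
    def test_hand_computed_single_hidden_unit(self):
        # x=(0.3,0.2): z1 = 0.3+0.2+0.5 = 1.0, relu active;
        # logits = (2*1+0.1, -1*1-0.1) = (2.1, -1.1)
        model = MLPModel(
            weights=[np.array([[1.0], [1.0]]), np.array([[2.0, -1.0]])],
            biases=[np.array([0.5]), np.array([0.1, -0.1])],
        )
        P = forward(model, np.array([[0.3, 0.2]]))
        expected0 = np.exp(2.1) / (np.exp(2.1) + np.exp(-1.1))
        assert P[0] == pytest.approx([expected0, 1 - expected0], abs=1e-12)

    def test_relu_gates_negative_preactivation(self):
        # x=(-1,-1): z1 = -2.5 -> relu 0 -> logits are the output biases
        model = MLPModel(
            weights=[np.array([[1.0], [1.0]]), np.array([[2.0, -1.0]])],
            biases=[np.array([0.5]), np.array([0.3, -0.3])],
        )
        P = forward(model, np.array([[-1.0, -1.0]]))
        expected0 = np.exp(0.3) / (np.exp(0.3) + np.exp(-0.3))
        assert P[0, 0] == pytest.approx(expected0, abs=1e-12)

    def test_logit_shift_invariance(self):
        model = init_model(4, 3, seed=1)
        shifted = model.copy()
        shifted.biases[-1] = shifted.biases[-1] + 7.5
        X = np.random.default_rng(2).normal(size=(5, 4))
        assert np.allclose(forward(model, X), forward(shifted, X), atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        X=arrays(
            float,
            (3, 4),
            elements=st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
        )
    )
    def test_softmax_rows_on_simplex_for_arbitrary_inputs(self, X):
        P = forward(init_model(4, 5, seed=0), X)
        assert (P >= 0).all()
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            forward(init_model(4, 3, seed=0), np.zeros((2, 5)))


class TestInputGradient:
    @pytest.mark.parametrize("loss", ["mse_softmax", "cross_entropy"])
    def test_matches_central_finite_differences(self, loss, rng):
        model = init_model(4, 3, seed=8)
        X = rng.normal(size=(5, 4))
        Y = np.eye(3)[rng.integers(0, 3, size=5)]
        g = input_gradient(model, X, Y, loss)
        g_fd = finite_difference_gradient(model, X, Y, loss)
        rel = np.abs(g - g_fd) / np.maximum(np.abs(g_fd), 1e-6)
        assert rel.max() <= 1e-4

    def test_matches_finite_differences_with_input_standardisation(self, rng):
        model = init_model(
            4, 3, seed=8,
            feature_mean=rng.normal(size=4), feature_scale=rng.uniform(0.5, 2.0, 4),
        )
        X = rng.normal(size=(5, 4))
        Y = np.eye(3)[rng.integers(0, 3, size=5)]
        g_fd = finite_difference_gradient(model, X, Y, "mse_softmax")
        rel = np.abs(input_gradient(model, X, Y) - g_fd) / np.maximum(np.abs(g_fd), 1e-6)
        assert rel.max() <= 1e-4

    def test_zero_at_perfect_prediction(self):
        # zero-weight model predicts uniform; with uniform targets the MSE
        # residual phi(x) - y vanishes identically, hence so does the gradient
        model = zero_model(k_in=3, c=4)
        X = np.random.default_rng(1).normal(size=(6, 3))
        Y = np.full((6, 4), 0.25)
        assert np.array_equal(input_gradient(model, X, Y), np.zeros((6, 3)))

    def test_batch_gradient_stacks_per_sample_gradients(self, rng):
        model = init_model(4, 3, seed=3)
        X = rng.normal(size=(5, 4))
        Y = np.eye(3)[rng.integers(0, 3, size=5)]
        full = input_gradient(model, X, Y)
        rows = [input_gradient(model, X[i : i + 1], Y[i : i + 1]) for i in range(5)]
        assert np.allclose(full, np.vstack(rows), atol=1e-12)


def gaussian_clusters(rng, n_per=100, sep=3.0):
    X = np.vstack(
        [
            rng.normal(loc=(-sep, 0), scale=0.5, size=(n_per, 2)),
            rng.normal(loc=(+sep, 0), scale=0.5, size=(n_per, 2)),
        ]
    )
    y = np.repeat([0, 1], n_per)
    return X, y, np.eye(2)[y]


class TestTrain:
    def test_separable_clusters_reach_perfect_training_accuracy(self, rng):
        X, y, Y = gaussian_clusters(rng)
        model = init_model(2, 2, seed=0, hidden=(16,))
        trained = train(model, X, Y, TrainConfig(epochs=100, seed=1))
        assert evaluate(trained, X, y)["accuracy"] == 1.0
        # beats the best constant predictor (p = (1/2, 1/2): 0.5 per sample)
        assert loss_value(trained, X, Y) < 0.5 * len(X)

    def test_loss_decreases_on_separable_fixture(self, rng):
        X, _, Y = gaussian_clusters(rng)
        model = init_model(2, 2, seed=0, hidden=(16,))
        trained = train(model, X, Y, TrainConfig(epochs=50, seed=1))
        assert trained.loss_curve_[-1] < trained.loss_curve_[0]

    def test_shuffled_labels_stay_at_chance_on_held_out_data(self, rng):
        X, _, _ = gaussian_clusters(rng, n_per=150)
        y = rng.permutation(np.repeat([0, 1], 150))
        Y = np.eye(2)[y]
        tr, te = np.arange(0, 200), np.arange(200, 300)
        model = init_model(2, 2, seed=0, hidden=(8,))
        trained = train(model, X[tr], Y[tr], TrainConfig(epochs=60, seed=1))
        acc = evaluate(trained, X[te], y[te])["accuracy"]
        # 3 SE band around chance for n=100 binary outcomes
        assert abs(acc - 0.5) <= 3 * 0.05

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        X, _, Y = gaussian_clusters(rng, n_per=10)
        model = init_model(2, 2, seed=5)
        out = train(model, X, Y, TrainConfig(epochs=0, seed=1))
        assert out.parameter_hash() == model.parameter_hash()

    def test_training_is_deterministic_given_seed(self, rng):
        X, _, Y = gaussian_clusters(rng, n_per=30)
        cfg = TrainConfig(epochs=10, seed=9)
        a = train(init_model(2, 2, seed=0), X, Y, cfg)
        b = train(init_model(2, 2, seed=0), X, Y, cfg)
        assert a.parameter_hash() == b.parameter_hash()

    def test_non_finite_loss_raises(self, rng):
        X, _, Y = gaussian_clusters(rng, n_per=10)
        model = init_model(2, 2, seed=0)
        model.weights[0][0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="non-finite"):
            train(model, X, Y, TrainConfig(epochs=1, seed=0))


class TestEvaluate:
    def test_hand_counted_confusion(self):
        # predictions (0, 1, 1) against truth (0, 1, 0)
        model = MLPModel(
            weights=[np.array([[10.0, -10.0]])], biases=[np.zeros(2)]
        )
        X = np.array([[1.0], [-1.0], [-1.0]])
        res = evaluate(model, X, np.array([0, 1, 0]))
        assert res["accuracy"] == pytest.approx(2 / 3)
        assert res["confusion"][0, 1] == 1
        assert res["confusion"].sum() == 3

    def test_perfect_predictions_give_diagonal_confusion(self):
        model = MLPModel(weights=[np.array([[10.0, -10.0]])], biases=[np.zeros(2)])
        X = np.array([[1.0], [-1.0]])
        res = evaluate(model, X, np.array([0, 1]))
        assert res["accuracy"] == 1.0
        assert np.array_equal(res["confusion"], np.eye(2, dtype=int))

    def test_row_normalised_rows_sum_to_one(self, rng):
        model = init_model(3, 4, seed=0)
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 4, size=20)
        res = evaluate(model, X, y)
        present = res["confusion"].sum(axis=1) > 0
        sums = np.asarray(res["confusion_normalized"]).sum(axis=1)
        assert np.allclose(sums[present], 1.0)

    def test_argmax_ties_break_toward_lower_class(self):
        res = evaluate(zero_model(k_in=2, c=3), np.zeros((4, 2)), np.zeros(4, dtype=int))
        assert (res["predictions"] == 0).all()
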