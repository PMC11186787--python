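"""GIN model: dense brute-force oracle, invariances, gradients, training."""

import numpy as np
import pytest
import scipy.sparse

from neuralsig.nn import (
    GNNModel,
    GraphExample,
    Tensor,
    TrainConfig,
    batch_examples,
    evaluate,
    predict,
    score_report,
    train,
)
from neuralsig.nn.autodiff import absolute


def dense_oracle_forward(model: GNNModel, features: np.ndarray, adj: np.ndarray):
    """Independent dense re-implementation of the eval-mode forward pass.

    Node loops and dense arithmetic only; reads the model's parameter
    arrays but shares no code with the vectorized implementation.
    """

    def linear(x, lin):
        return x @ lin.weight.data + lin.bias.data

    def batchnorm(x, bn):
        return (x - bn.running_mean) / np.sqrt(bn.running_var + bn.eps) * (
            bn.gamma.data
        ) + bn.beta.data

    h = features.astype(float)
    adj_self = adj + np.eye(len(adj))
    for conv in model.convs:
        combined = np.empty((len(h), h.shape[1]))
        for v in range(len(h)):
            neighbor_sum = np.zeros(h.shape[1])
            for u in range(len(h)):
                if adj_self[v, u]:
                    neighbor_sum += np.maximum(h[u], 0.0)
            combined[v] = (1.0 + conv.epsilon.data) * h[v] + neighbor_sum
        z = np.maximum(linear(combined, conv.lin1), 0.0)
        z = linear(z, conv.lin2)
        z = batchnorm(z, conv.norm)
        h = np.where(z > 0, z, 0.2 * z)
    z = linear(h, model.merge)
    pooled = z.mean(axis=0, keepdims=True)
    a = np.maximum(linear(pooled, model.head_lin1), 0.0)
    a = batchnorm(a, model.head_norm)
    return float(linear(a, model.head_lin2)[0, 0])


def random_example(rng, n_nodes, in_dim, target=None):
    adj = (rng.random((n_nodes, n_nodes)) < 0.5).astype(float)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    features = rng.normal(size=(n_nodes, in_dim))
    example = GraphExample(
        features=features,
        adjacency=scipy.sparse.csr_matrix(adj + np.eye(n_nodes)),
        target=target,
    )
    return example, adj


def randomize_running_stats(model, rng):
    for bn in [c.norm for c in model.convs] + [model.head_norm]:
        bn.running_mean = rng.normal(size=bn.running_mean.shape)
        bn.running_var = rng.uniform(0.5, 2.0, size=bn.running_var.shape)
    for conv in model.convs:
        conv.epsilon.data = np.asarray(rng.normal(0.0, 0.2))


class TestForward:
    def test_matches_dense_oracle_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for draw in range(100):
            model = GNNModel(in_dim=3, hidden_dim=4, latent_dim=3, seed=draw)
            randomize_running_stats(model, rng)
            n = int(rng.integers(1, 6))
            example, adj = random_example(rng, n, 3)
            features, adjacency, pool, _ = batch_examples([example])
            out = model.forward(features, adjacency, pool, training=False)
            oracle = dense_oracle_forward(model, example.features, adj)
            assert out.data[0, 0] == pytest.approx(oracle, abs=1e-6)

    def test_node_permutation_leaves_prediction_unchanged(self):
        rng = np.random.default_rng(1)
        model = GNNModel(in_dim=4, hidden_dim=6, latent_dim=4, seed=2)
        randomize_running_stats(model, rng)
        example, adj = random_example(rng, 5, 4)
        base = predict(model, [example])[0]
        for _ in range(5):
            perm = rng.permutation(5)
            permuted = GraphExample(
                features=example.features[perm],
                adjacency=scipy.sparse.csr_matrix(
                    example.adjacency.toarray()[np.ix_(perm, perm)]
                ),
            )
            assert predict(model, [permuted])[0] == pytest.approx(base, abs=1e-9)

    def test_single_node_combine_doubles_nonnegative_input(self):
        # identity MLP, eps=0, neutralized norm: pre-activation equals 2x
        model = GNNModel(in_dim=2, hidden_dim=2, latent_dim=2, n_layers=1, seed=0,
                         dropout_rate=0.0)
        conv = model.convs[0]
        for lin in (conv.lin1, conv.lin2):
            lin.weight.data = np.eye(2)
            lin.bias.data = np.zeros(2)
        conv.epsilon.data = np.asarray(0.0)
        conv.norm.running_mean = np.zeros(2)
        conv.norm.running_var = np.full(2, 1.0 - conv.norm.eps)
        x = np.array([[3.0, 1.5]])
        adjacency = scipy.sparse.csr_matrix(np.array([[1.0]]))
        pool = scipy.sparse.csr_matrix(np.array([[1.0]]))
        h = conv(Tensor(x), adjacency, training=False, rng=None)
        np.testing.assert_allclose(h.data, 2.0 * x, atol=1e-6)

    def test_all_zero_features_and_biases_give_zero_scores(self):
        model = GNNModel(in_dim=3, hidden_dim=4, latent_dim=3, seed=5)
        for lin in (
            [c.lin1 for c in model.convs]
            + [c.lin2 for c in model.convs]
            + [model.merge, model.head_lin1, model.head_lin2]
        ):
            lin.bias.data = np.zeros_like(lin.bias.data)
        example = GraphExample(
            features=np.zeros((4, 3)),
            adjacency=scipy.sparse.csr_matrix(np.eye(4)),
        )
        assert predict(model, [example])[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_subgraph_rejected(self):
        model = GNNModel(in_dim=3, seed=0)
        with pytest.raises(ValueError, match="empty"):
            model.forward(
                np.zeros((0, 3)),
                scipy.sparse.csr_matrix((0, 0)),
                scipy.sparse.csr_matrix((1, 0)),
            )

    def test_eval_mode_is_deterministic(self):
        rng = np.random.default_rng(4)
        model = GNNModel(in_dim=3, seed=3)
        example, _ = random_example(rng, 4, 3)
        assert predict(model, [example])[0] == predict(model, [example])[0]


class TestGradients:
    def test_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        model = GNNModel(in_dim=4, hidden_dim=5, latent_dim=3, seed=1,
                         dropout_rate=0.0)
        example, _ = random_example(rng, 2, 4, target=0.4)
        features, adjacency, pool, targets = batch_examples([example])

        def loss_value():
            out = model.forward(
                features, adjacency, pool, training=True,
                rng=np.random.default_rng(0),
            )
            return float(absolute(out - Tensor(targets[:, None])).mean().data)

        out = model.forward(
            features, adjacency, pool, training=True, rng=np.random.default_rng(0)
        )
        loss = absolute(out - Tensor(targets[:, None])).mean()
        loss.backward()
        h = 1e-6
        for p in model.parameters():
            grad = p.grad if p.grad is not None else np.zeros_like(p.data)
            it = np.nditer(p.data, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p.data[idx]
                p.data[idx] = orig + h
                fp = loss_value()
                p.data[idx] = orig - h
                fm = loss_value()
                p.data[idx] = orig
                fd = (fp - fm) / (2 * h)
                denom = max(abs(fd), abs(grad[idx]), 1e-6)
                assert abs(fd - grad[idx]) / denom < 1e-4


class TestTraining:
    def _examples(self, rng, n, in_dim=5):
        out = []
        for _ in range(n):
            example, _ = random_example(rng, int(rng.integers(3, 7)), in_dim)
            # target: a fixed linear readout of mean features (learnable)
            example.target = float(
                0.4 + 0.1 * np.tanh(example.features.mean())
            )
            out.append(example)
        return out

    def test_zero_epochs_leave_parameters_unchanged(self):
        rng = np.random.default_rng(0)
        model = GNNModel(in_dim=5, seed=0)
        before = [p.data.copy() for p in model.parameters()]
        train(model, self._examples(rng, 4), TrainConfig(epochs=0, seed=0))
        for b, p in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_training_reduces_loss_on_learnable_task(self):
        rng = np.random.default_rng(1)
        model = GNNModel(in_dim=5, hidden_dim=8, latent_dim=4, seed=1)
        history = train(
            model,
            self._examples(rng, 64),
            TrainConfig(epochs=15, batch_size=32, learning_rate=1e-3, seed=2),
        )
        assert history[-1] < history[0]

    def test_identical_seeds_give_identical_histories(self):
        rng = np.random.default_rng(2)
        examples = self._examples(rng, 16)
        histories = []
        for _ in range(2):
            model = GNNModel(in_dim=5, seed=7)
            histories.append(
                train(model, examples, TrainConfig(epochs=3, seed=11))
            )
        assert histories[0] == histories[1]

    def test_negative_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=-1)


class TestEvaluation:
    def test_perfect_predictions_score_one(self):
        truth = np.array([0.2, 0.5, 0.7, 0.3])
        report = score_report(truth.copy(), truth, cutoff=0.41)
        assert report["r2"] == pytest.approx(1.0)
        assert report["f1"] == pytest.approx(1.0)

    def test_mean_prediction_scores_zero_r2(self):
        truth = np.array([0.2, 0.4, 0.6])
        preds = np.full(3, truth.mean())
        assert score_report(preds, truth)["r2"] == pytest.approx(0.0)

    def test_f1_from_confusion_counts(self):
        # TP=2, FP=1, FN=1 -> F1 = 2/3
        truth = np.array([0.5, 0.6, 0.3, 0.5])
        preds = np.array([0.5, 0.6, 0.5, 0.3])
        assert score_report(preds, truth, cutoff=0.41)["f1"] == pytest.approx(2 / 3)

    def test_constant_truth_warns_and_reports_no_r2(self):
        with pytest.warns(UserWarning, match="constant"):
            report = score_report(np.array([0.1, 0.2]), np.array([0.5, 0.5]))
        assert report["r2"] is None

    def test_evaluate_requires_targets(self):
        model = GNNModel(in_dim=2, seed=0)
        example = GraphExample(
            features=np.zeros((2, 2)),
            adjacency=scipy.sparse.csr_matrix(np.eye(2)),
        )
        with pytest.raises(ValueError, match="truth"):
            evaluate(model, [example])
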