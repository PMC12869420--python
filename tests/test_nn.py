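import numpy as np
import pytest

from enggnn.graph import AdjacencyMatrix
from enggnn.nn import (
    EngGNNNetwork,
    GEDFNNetwork,
    TrainingConfig,
    cross_entropy_loss,
    masked_dense_forward,
    relu,
    train_network,
)


def identity(x):
    return x


class TestMaskedDenseForward:
    def test_identity_mask_is_per_feature_scaling(self):
        W = np.diag([3.0, 4.0])
        out = masked_dense_forward([[1.0, 2.0]], W, np.zeros(2), np.eye(2), identity)
        np.testing.assert_allclose(out, [[3.0, 8.0]])

    def test_all_ones_mask_equals_dense_layer(self):
        rng = np.random.default_rng(0)
        X, W, b = rng.standard_normal((4, 3)), rng.standard_normal((3, 3)), rng.standard_normal(3)
        out = masked_dense_forward(X, W, b, np.ones((3, 3)), identity)
        np.testing.assert_allclose(out, X @ W + b)

    def test_hand_computed_relu_case(self):
        W = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = masked_dense_forward([[1.0, 1.0]], W, np.ones(2), np.ones((2, 2)), relu)
        np.testing.assert_allclose(out, [[5.0, 7.0]])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            masked_dense_forward(np.ones((1, 3)), np.ones((2, 2)), np.zeros(2), np.ones((2, 2)))

    def test_brute_force_oracle(self):
        """Per-unit accumulation loop sum_j X_ij W_ju mask_ju + b_u."""
        rng = np.random.default_rng(42)
        X = rng.standard_normal((10, 10))
        W = rng.standard_normal((10, 10))
        b = rng.standard_normal(10)
        mask = (rng.uniform(size=(10, 10)) < 0.4).astype(float)
        expected = np.zeros((10, 10))
        for i in range(10):
            for u in range(10):
                acc = b[u]
                for j in range(10):
                    if mask[j, u] == 1:
                        acc += X[i, j] * W[j, u]
                expected[i, u] = max(acc, 0.0)
        out = masked_dense_forward(X, W, b, mask, relu)
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy_loss([[1, 0]], [[1.0, 0.0]]) == 0.0

    def test_half_probability_is_ln2(self):
        loss = cross_entropy_loss([[1, 0]], [[0.5, 0.5]])
        np.testing.assert_allclose(loss, np.log(2), atol=1e-12)

    def test_uniform_batch_is_ln2_regardless_of_labels(self):
        y = np.eye(2)[[0, 1, 1, 0]]
        p = np.full((4, 2), 0.5)
        np.testing.assert_allclose(cross_entropy_loss(y, p), np.log(2))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss([[1, 0]], [[1.5, -0.5]])


def random_mask(rng, p):
    m = (rng.uniform(size=(p, p)) < 0.3).astype(float)
    np.fill_diagonal(m, 1.0)
    return m


class TestGEDFNForward:
    def test_zero_params_give_zero_embedding(self):
        p = 6
        net = GEDFNNetwork(np.eye(p))
        rng = np.random.default_rng(0)
        params = {k: np.zeros_like(v) for k, v in net.init_params(rng).items()}
        emb = net.embed(params, rng.standard_normal((3, p)))
        np.testing.assert_array_equal(emb, np.zeros((3, 16)))

    def test_eval_mode_deterministic(self):
        rng = np.random.default_rng(1)
        net = GEDFNNetwork(random_mask(rng, 8))
        params = net.init_params(rng)
        X = rng.standard_normal((5, 8))
        p1, _ = net.forward(params, X)
        p2, _ = net.forward(params, X)
        np.testing.assert_array_equal(p1, p2)

    def test_embedding_matches_explicit_matrix_products(self):
        """Independent oracle: recompute the whole forward pass as a plain
        sequence of numpy expressions."""
        rng = np.random.default_rng(2)
        p = 7
        mask = random_mask(rng, p)
        net = GEDFNNetwork(mask)
        params = net.init_params(rng)
        X = rng.standard_normal((4, p))
        h1 = np.maximum(X @ (params["b0.W1"] * mask) + params["b0.b1"], 0)
        h2 = np.maximum(h1 @ params["b0.W2"] + params["b0.b2"], 0)
        h3 = np.maximum(h2 @ params["b0.W3"] + params["b0.b3"], 0)
        np.testing.assert_allclose(net.embed(params, X), h3, atol=1e-6)
        logits = h3 @ params["head.W"] + params["head.b"]
        expected = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        probs, _ = net.forward(params, X)
        np.testing.assert_allclose(probs, expected, atol=1e-10)

    def test_mask_requires_unit_diagonal(self):
        with pytest.raises(ValueError):
            GEDFNNetwork(np.zeros((3, 3)))


class TestMaskOpacity:
    @pytest.mark.parametrize("seed", range(4))
    def test_perturbing_unsupported_weights_never_changes_output(self, seed):
        rng = np.random.default_rng(seed)
        p = 9
        mask = random_mask(rng, p)
        net = GEDFNNetwork(mask)
        params = net.init_params(rng)
        X = rng.standard_normal((6, p))
        base, _ = net.forward(params, X)
        zeros = np.argwhere(mask == 0)
        for j, u in zeros[rng.permutation(len(zeros))[:10]]:
            perturbed = {k: v.copy() for k, v in params.items()}
            perturbed["b0.W1"][j, u] += rng.standard_normal() * 100
            out, _ = net.forward(perturbed, X)
            np.testing.assert_array_equal(out, base)

    def test_gradient_outside_support_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        p = 8
        mask = random_mask(rng, p)
        net = GEDFNNetwork(mask)
        params = net.init_params(rng)
        X = rng.standard_normal((5, p))
        y = np.eye(2)[rng.integers(0, 2, 5)]
        _, cache = net.forward(params, X, train=False)
        grads = net.backward(params, cache, y)
        assert (grads["b0.W1"][mask == 0] == 0).all()

    def test_dual_network_opacity(self):
        rng = np.random.default_rng(3)
        p = 6
        me, mg = random_mask(rng, p), random_mask(rng, p)
        net = EngGNNNetwork(me, mg)
        params = net.init_params(rng)
        X = rng.standard_normal((4, p))
        base, _ = net.forward(params, X)
        for key, mask in (("e.W1", me), ("g.W1", mg)):
            zeros = np.argwhere(mask == 0)
            if len(zeros) == 0:
                continue
            j, u = zeros[0]
            perturbed = {k: v.copy() for k, v in params.items()}
            perturbed[key][j, u] = 1e6
            out, _ = net.forward(perturbed, X)
            np.testing.assert_array_equal(out, base)


def separable_toy(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 2)) * 0.3 + np.c_[y * 4.0 - 2.0, -(y * 4.0 - 2.0)]
    return X, y


class TestTraining:
    def test_separable_problem_is_learned(self):
        X, y = separable_toy()
        net = GEDFNNetwork(np.ones((2, 2)))
        cfg = TrainingConfig(learning_rate=0.01, epochs=30, seed=0, monitor="train")
        params, trace = train_network(net, X, y, cfg)
        probs, _ = net.forward(params, X)
        acc = (probs.argmax(1) == y).mean()
        assert acc >= 0.95
        assert min(trace) == trace[int(np.argmin(trace))]

    def test_early_stopping_patience(self):
        rng = np.random.default_rng(0)
        X, y = rng.standard_normal((80, 2)), rng.integers(0, 2, 80)
        net = GEDFNNetwork(np.ones((2, 2)))
        # pure-noise labels: the validation loss soon rises, so patience=1 halts
        cfg = TrainingConfig(
            learning_rate=0.05, epochs=50, early_stopping_patience=1, seed=0
        )
        _, trace = train_network(net, X, y, cfg)
        assert len(trace) < 50

    def test_same_seed_reproducible(self):
        X, y = separable_toy(120, seed=5)
        net = GEDFNNetwork(np.ones((2, 2)))
        cfg = TrainingConfig(learning_rate=0.005, epochs=10, seed=9)
        p1, t1 = train_network(net, X, y, cfg)
        p2, t2 = train_network(net, X, y, cfg)
        assert t1 == t2
        for k in p1:
            np.testing.assert_array_equal(p1[k], p2[k])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)
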