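import numpy as np
import pytest

from enggnn.graph import FeatureGraph
from enggnn.simulate import (
    SimulationConfig,
    build_covariance,
    generate_ba_graph,
    generate_outcome,
    sample_features,
    select_true_features,
    simulate_dataset,
)


class TestBAGraph:
    def test_m1_yields_tree(self):
        g = generate_ba_graph(5, 1, seed=0)
        assert g.n_edges == 4 and not g.directed

    def test_seed_reproducible(self):
        assert generate_ba_graph(100, 1, seed=3) == generate_ba_graph(100, 1, seed=3)

    def test_degree_distribution_right_skewed(self):
        g = generate_ba_graph(2000, 1, seed=1)
        deg = g.degrees()
        assert deg.max() > 5 * np.median(deg)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            generate_ba_graph(5, 0)
        with pytest.raises(ValueError):
            generate_ba_graph(5, 5)


class TestCovariance:
    def test_triangular_two_node_closed_form(self):
        """One edge, weight w: (I-A*)^-1 = [[1, w], [0, 1]] so
        Sigma = [[1+w^2, w], [w, 1]]; with w=0.5 -> [[1.25, 0.5], [0.5, 1]]."""
        g = FeatureGraph(["a", "b"], [(0, 1)])
        a_star, sigma = build_covariance(
            g, weight_range=(0.5, 0.5), orientation="triangular"
        )
        np.testing.assert_allclose(a_star, [[0, 0.5], [0, 0]])
        np.testing.assert_allclose(sigma, [[1.25, 0.5], [0.5, 1.0]])

    def test_no_edges_gives_identity(self):
        g = FeatureGraph(["a", "b", "c"])
        for orientation in ("symmetric", "triangular"):
            _, sigma = build_covariance(g, orientation=orientation)
            np.testing.assert_allclose(sigma, np.eye(3))

    @pytest.mark.parametrize("orientation", ["symmetric", "triangular"])
    def test_random_graph_positive_definite(self, orientation):
        g = generate_ba_graph(20, 1, seed=5)
        _, sigma = build_covariance(g, seed=5, orientation=orientation)
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-9)
        assert np.linalg.eigvalsh(sigma).min() > 0

    def test_symmetric_orientation_weights_both_triangles(self):
        g = FeatureGraph(["a", "b"], [(0, 1)])
        a_star, _ = build_covariance(g, weight_range=(2.0, 2.0), orientation="symmetric")
        np.testing.assert_allclose(a_star, [[0, 2], [2, 0]])


class TestSampleFeatures:
    def test_identity_covariance_monte_carlo(self):
        X = sample_features(20000, np.eye(10), mu_x_range=(0.0, 0.0), seed=0)
        emp = np.cov(X.T, bias=True)
        assert np.linalg.norm(emp - np.eye(10)) < 0.1

    def test_seed_reproducible(self):
        a = sample_features(50, np.eye(3), seed=2)
        b = sample_features(50, np.eye(3), seed=2)
        np.testing.assert_array_equal(a, b)

    def test_column_means_near_mu_range(self):
        X = sample_features(5000, np.eye(4), mu_x_range=(7.0, 13.0), seed=1)
        se = 4 / np.sqrt(5000)
        assert ((X.mean(0) > 7 - se) & (X.mean(0) < 13 + se)).all()

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            sample_features(10, -np.eye(2), seed=0)


class TestTrueFeatureSelection:
    def path_graph(self):
        return FeatureGraph(["A", "B", "C"], [(0, 1), (1, 2)])

    def test_path_graph_centrality_and_expansion(self):
        """On A-B-C, closeness ranks B highest; the single seed comes from
        Hc={B} and one-hop expansion covers the whole path."""
        seeds, mask = select_true_features(self.path_graph(), pt=1 / 3, seed=0)
        np.testing.assert_array_equal(seeds, [1])
        np.testing.assert_array_equal(mask, [1, 1, 1])

    def test_mask_contains_seeds(self):
        g = generate_ba_graph(40, 1, seed=2)
        seeds, mask = select_true_features(g, pt=0.2, seed=2)
        assert mask[seeds].all()

    def test_stratified_counts(self):
        g = generate_ba_graph(100, 1, seed=0)
        seeds, _ = select_true_features(g, pt=0.1, seed=0)
        assert len(seeds) == 10

    def test_too_small_pt_rejected(self):
        with pytest.raises(ValueError):
            select_true_features(self.path_graph(), pt=0.1)


class TestOutcome:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.X = rng.standard_normal((200, 5))
        self.mask = np.array([1, 1, 0, 0, 1])
        self.beta = rng.uniform(-5, 5, 3)

    def test_monotone_in_eta(self):
        y = generate_outcome(self.X, self.mask, 1.0, self.beta, s=0.6)
        eta = 1.0 + self.X[:, [0, 1, 4]] @ self.beta
        assert y[np.argmax(eta)] == 1 and y[np.argmin(eta)] == 0
        # labels are a threshold on eta: no positive below any negative
        assert eta[y == 1].min() > eta[y == 0].max()

    def test_s_zero_boundary(self):
        y = generate_outcome(self.X, self.mask, 0.0, self.beta, s=0.0)
        assert y.sum() == len(y) - 1
        assert y[np.argmin(0.0 + self.X[:, [0, 1, 4]] @ self.beta)] == 0

    def test_intercept_shift_invariance(self):
        """Min-max absorbs any shift of the linear predictor."""
        y1 = generate_outcome(self.X, self.mask, -5.0, self.beta, s=0.6)
        y2 = generate_outcome(self.X, self.mask, 123.0, self.beta, s=0.6)
        np.testing.assert_array_equal(y1, y2)

    def test_quantile_mode_positive_fraction(self):
        y = generate_outcome(self.X, self.mask, 0.0, self.beta, s=0.6)
        assert abs(y.mean() - 0.4) < 0.02

    def test_rescaled_mode_is_more_imbalanced(self):
        y = generate_outcome(
            self.X, self.mask, 0.0, self.beta, s=0.6, threshold_mode="rescaled"
        )
        assert 0 < y.mean() < 0.4


class TestSimulateDataset:
    def test_default_scale_contract(self):
        sim = simulate_dataset(SimulationConfig(p=60, n=400, pt=0.05, seed=1))
        assert sim.data.X.shape == (400, 60)
        assert sim.true_feature_mask.sum() >= 3  # seeds plus neighbours
        assert set(np.unique(sim.data.y)) == {0, 1}
        assert sim.graph.node_labels == sim.data.feature_names

    def test_reproducible(self):
        cfg = SimulationConfig(p=40, n=200, pt=0.1, seed=9)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        np.testing.assert_array_equal(a.data.X, b.data.X)
        np.testing.assert_array_equal(a.data.y, b.data.y)
        np.testing.assert_array_equal(a.true_feature_mask, b.true_feature_mask)

    def test_mild_imbalance_across_seeds(self):
        fracs = [
            simulate_dataset(SimulationConfig(p=30, n=200, pt=0.2, seed=s)).data.y.mean()
            for s in range(5)
        ]
        assert all(0 < f <= 0.5 for f in fracs)

    def test_signal_in_true_features(self):
        """A linear classifier on the true features beats one on an
        equal-sized random non-informative set."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        acc_true, acc_null = [], []
        for s in range(5):
            sim = simulate_dataset(SimulationConfig(p=50, n=400, pt=0.1, seed=s))
            rng = np.random.default_rng(s)
            true_idx = np.flatnonzero(sim.true_feature_mask)
            null_pool = np.flatnonzero(sim.true_feature_mask == 0)
            null_idx = rng.choice(null_pool, size=min(len(true_idx), len(null_pool)), replace=False)
            for idx, acc in ((true_idx, acc_true), (null_idx, acc_null)):
                clf = LogisticRegression(max_iter=2000)
                score = cross_val_score(clf, sim.data.X[:, idx], sim.data.y, cv=3).mean()
                acc.append(score)
        assert np.mean(acc_true) > np.mean(acc_null)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p=2)
        with pytest.raises(ValueError):
            SimulationConfig(pt=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(threshold_mode="bogus")
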