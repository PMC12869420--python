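"""Fitted classifiers: the dual-graph model and its baselines.

:class:`EngGNNClassifier` is the full dual-graph model: the external
undirected graph ``Ge`` masks one GEDFN branch, a directed graph ``Gg``
extracted from a boosted-tree ensemble fitted on the same training split masks
the other, and the concatenated embeddings feed a small fusion network.  The
generated graph is part of the learned model, so the ensemble is always fitted
on the training rows only, as are the Z-score normalization statistics stored
in the model and reapplied at prediction time.

``fit_baseline`` provides the comparison models: single-graph GEDFNs (external
graph, boosted-tree graph, random-forest graph), the graph-free DFN (all-ones
mask), and the raw tree ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .data import ExpressionDataset, ZScoreStats, apply_zscore, zscore_normalize
from .graph import FeatureGraph, augment_with_self_loops, to_adjacency
from .nn import EngGNNNetwork, GEDFNNetwork, TrainingConfig, train_network
from .tree_graph import EnsembleGraphConfig, build_generated_graph, make_estimator

__all__ = [
    "PredictionResult",
    "EngGNNClassifier",
    "GEDFNClassifier",
    "TreeEnsembleClassifier",
    "fit_enggnn",
    "fit_baseline",
    "BASELINE_KINDS",
]

BASELINE_KINDS = (
    "gedfn_e",
    "gedfn_xgb",
    "gedfn_rf",
    "dfn",
    "boosted_trees",
    "random_forest",
)


@dataclass
class PredictionResult:
    class_probs: np.ndarray
    predicted_labels: np.ndarray

    def __post_init__(self) -> None:
        rowsum = self.class_probs.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            raise ValueError("class probability rows must sum to 1")


def _graph_mask(graph: FeatureGraph) -> np.ndarray:
    return augment_with_self_loops(to_adjacency(graph)).values


def _check_alignment(graph: FeatureGraph, data: ExpressionDataset) -> None:
    if graph.p != data.p or graph.node_labels != data.feature_names:
        raise ValueError(
            "feature graph labels do not align with the dataset's feature names"
        )


class EngGNNClassifier:
    """Dual-graph neural network classifier.

    Parameters
    ----------
    external_graph
        Undirected feature graph ``Ge`` aligned with the training features.
    tree_config
        Hyperparameters of the graph-generating boosted ensemble; the seed is
        taken from ``train_config`` when unset.
    train_config
        Optimizer/regularization settings shared by both branches and the head.
    """

    def __init__(
        self,
        external_graph: FeatureGraph,
        tree_config: EnsembleGraphConfig | None = None,
        train_config: TrainingConfig | None = None,
    ) -> None:
        if external_graph.directed:
            raise ValueError("the external graph must be undirected")
        self.external_graph = external_graph
        self.train_config = train_config or TrainingConfig()
        self.tree_config = tree_config or EnsembleGraphConfig(
            seed=self.train_config.seed
        )
        self.generated_graph: FeatureGraph | None = None
        self.params: dict[str, np.ndarray] | None = None
        self.loss_trace: list[float] = []
        self.stats: ZScoreStats | None = None
        self.feature_names: list[str] = []
        self._net: EngGNNNetwork | None = None

    def fit(self, train: ExpressionDataset) -> "EngGNNClassifier":
        _check_alignment(self.external_graph, train)
        norm, self.stats = zscore_normalize(train)
        self.feature_names = list(train.feature_names)
        self.generated_graph = build_generated_graph(norm, self.tree_config)
        self._net = EngGNNNetwork(
            _graph_mask(self.external_graph), _graph_mask(self.generated_graph)
        )
        self.params, self.loss_trace = train_network(
            self._net, norm.X, norm.y, self.train_config
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        Xn = apply_zscore(X, self.stats)
        probs, _ = self._net.forward(self.params, Xn, train=False)
        return probs

    def predict(self, X: np.ndarray) -> PredictionResult:
        probs = self.predict_proba(X)
        return PredictionResult(probs, probs.argmax(axis=1).astype(np.int64))

    # -- importance hooks ---------------------------------------------------
    def input_weights(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """First-layer weights and masks per branch: {'ge': (W, Ã), 'gg': ...}."""
        if self.params is None:
            raise RuntimeError("model is not fitted")
        return {
            "ge": (self.params["e.W1"], self._net.mask_e),
            "gg": (self.params["g.W1"], self._net.mask_g),
        }


class GEDFNClassifier:
    """Single-branch GEDFN (or DFN when ``graph`` is None → all-ones mask)."""

    def __init__(
        self,
        graph: FeatureGraph | None = None,
        graph_source: str = "external",
        tree_config: EnsembleGraphConfig | None = None,
        train_config: TrainingConfig | None = None,
    ) -> None:
        if graph_source not in ("external", "boosted", "random_forest", "dense"):
            raise ValueError(f"unknown graph_source {graph_source!r}")
        self.graph = graph
        self.graph_source = graph_source
        self.train_config = train_config or TrainingConfig()
        self.tree_config = tree_config
        self.params: dict[str, np.ndarray] | None = None
        self.loss_trace: list[float] = []
        self.stats: ZScoreStats | None = None
        self.feature_names: list[str] = []
        self._net: GEDFNNetwork | None = None

    def fit(self, train: ExpressionDataset) -> "GEDFNClassifier":
        norm, self.stats = zscore_normalize(train)
        self.feature_names = list(train.feature_names)
        if self.graph_source == "external":
            if self.graph is None:
                raise ValueError("external graph_source requires a graph")
            _check_alignment(self.graph, train)
            mask = _graph_mask(self.graph)
        elif self.graph_source == "dense":
            mask = np.ones((train.p, train.p))
        else:
            cfg = self.tree_config or EnsembleGraphConfig(
                ensemble_kind=self.graph_source
                if self.graph_source == "random_forest"
                else "boosted",
                seed=self.train_config.seed,
            )
            self.graph = build_generated_graph(norm, cfg)
            mask = _graph_mask(self.graph)
        self._net = GEDFNNetwork(mask)
        self.params, self.loss_trace = train_network(
            self._net, norm.X, norm.y, self.train_config
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        Xn = apply_zscore(X, self.stats)
        probs, _ = self._net.forward(self.params, Xn, train=False)
        return probs

    def predict(self, X: np.ndarray) -> PredictionResult:
        probs = self.predict_proba(X)
        return PredictionResult(probs, probs.argmax(axis=1).astype(np.int64))

    def input_weights(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        key = "ge" if self.graph_source in ("external", "dense") else "gg"
        return {key: (self.params["b0.W1"], self._net.mask)}


class TreeEnsembleClassifier:
    """Boosted-tree or random-forest baseline with native feature importance."""

    def __init__(
        self,
        kind: str = "boosted",
        config: EnsembleGraphConfig | None = None,
        seed: int = 0,
    ) -> None:
        if kind not in ("boosted", "random_forest"):
            raise ValueError("kind must be 'boosted' or 'random_forest'")
        self.config = config or EnsembleGraphConfig(ensemble_kind=kind, seed=seed)
        self.kind = self.config.ensemble_kind
        self.estimator = None
        self.stats: ZScoreStats | None = None
        self.feature_names: list[str] = []

    def fit(self, train: ExpressionDataset) -> "TreeEnsembleClassifier":
        norm, self.stats = zscore_normalize(train)
        self.feature_names = list(train.feature_names)
        self.estimator = make_estimator(self.config, train.p)
        self.estimator.fit(norm.X, norm.y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.estimator is None:
            raise RuntimeError("model is not fitted")
        return self.estimator.predict_proba(apply_zscore(X, self.stats))

    def predict(self, X: np.ndarray) -> PredictionResult:
        probs = self.predict_proba(X)
        return PredictionResult(probs, probs.argmax(axis=1).astype(np.int64))

    def native_importance(self) -> np.ndarray:
        """Gain importance (boosted) or Gini mean-decrease-in-impurity (RF).

        Features never used for a split score 0.
        """
        if self.estimator is None:
            raise RuntimeError("model is not fitted")
        p = len(self.feature_names)
        scores = np.zeros(p)
        if self.kind == "boosted":
            gain = self.estimator.get_booster().get_score(importance_type="gain")
            for name, value in gain.items():
                scores[int(name.lstrip("f"))] = value
        else:
            scores[:] = self.estimator.feature_importances_
        return scores


def fit_enggnn(
    train: ExpressionDataset,
    external_graph: FeatureGraph,
    train_config: TrainingConfig | None = None,
    tree_config: EnsembleGraphConfig | None = None,
) -> EngGNNClassifier:
    """Convenience wrapper: construct and fit the dual-graph model."""
    model = EngGNNClassifier(external_graph, tree_config, train_config)
    return model.fit(train)


def fit_baseline(
    kind: str,
    train: ExpressionDataset,
    external_graph: FeatureGraph | None = None,
    train_config: TrainingConfig | None = None,
    tree_config: EnsembleGraphConfig | None = None,
):
    """Fit one of the comparison models by name.

    ``gedfn_e`` needs ``external_graph``; the tree-graph GEDFNs and the raw
    ensembles build everything from the training data.
    """
    cfg = train_config or TrainingConfig()
    if kind == "gedfn_e":
        return GEDFNClassifier(
            external_graph, "external", tree_config, cfg
        ).fit(train)
    if kind == "gedfn_xgb":
        return GEDFNClassifier(None, "boosted", tree_config, cfg).fit(train)
    if kind == "gedfn_rf":
        return GEDFNClassifier(None, "random_forest", tree_config, cfg).fit(train)
    if kind == "dfn":
        return GEDFNClassifier(None, "dense", tree_config, cfg).fit(train)
    if kind == "boosted_trees":
        return TreeEnsembleClassifier("boosted", tree_config, seed=cfg.seed).fit(train)
    if kind == "random_forest":
        return TreeEnsembleClassifier("random_forest", tree_config, seed=cfg.seed).fit(
            train
        )
    raise ValueError(f"unknown baseline kind {kind!r}")
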