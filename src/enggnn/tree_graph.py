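"""Directed feature graphs extracted from fitted tree ensembles.

Each fitted decision tree defines a directed graph over the features it
splits on: whenever an internal node splitting on feature ``f`` has a child
that is itself an internal node splitting on ``f'``, the tree contributes the
edge ``f → f'`` (the hierarchical splitting order).  Per-tree graphs are
unioned across the ensemble into the generated graph ``Gg``, embedded in the
full ``p``-feature label space so never-selected features remain isolated
nodes; self-loops are added later when the adjacency mask is built.

The default ensemble is gradient-boosted trees (xgboost, binary logistic
objective); a random-forest ensemble backs the corresponding ablation
baseline.  The number of trees defaults to ``0.2·p``, scaling model
complexity with dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset
from .graph import FeatureGraph, union_graphs

__all__ = [
    "TreeNode",
    "DecisionTreeStructure",
    "EnsembleGraphConfig",
    "default_n_trees",
    "fit_ensemble",
    "extract_tree_graph",
    "build_generated_graph",
    "make_estimator",
]


@dataclass(frozen=True)
class TreeNode:
    node_id: int
    is_leaf: bool
    split_feature_index: int | None = None
    left_child: int | None = None
    right_child: int | None = None


@dataclass
class DecisionTreeStructure:
    """Parsed binary tree: a dict of nodes rooted at id 0."""

    nodes: dict[int, TreeNode]

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if not n.is_leaf]


@dataclass
class EnsembleGraphConfig:
    """Hyperparameters of the graph-generating ensemble.

    ``n_trees=None`` derives the ensemble size from the feature count as
    ``max(1, round(0.2 p))``.  Boosting defaults (depth 6, learning rate 0.3,
    L2 regularization 1, binary logistic objective) are the ecosystem defaults
    of the sparsity-aware boosting implementation.
    """

    n_trees: int | None = None
    ensemble_kind: str = "boosted"  # or "random_forest"
    max_depth: int = 6
    learning_rate: float = 0.3
    reg_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_kind not in ("boosted", "random_forest"):
            raise ValueError("ensemble_kind must be 'boosted' or 'random_forest'")
        if self.n_trees is not None and self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolve_n_trees(self, p: int) -> int:
        return self.n_trees if self.n_trees is not None else default_n_trees(p)


def default_n_trees(p: int) -> int:
    """Ensemble size proportional to feature count: ``max(1, round(0.2 p))``."""
    if p < 1:
        raise ValueError("feature count must be >= 1")
    return max(1, int(np.floor(0.2 * p + 0.5)))


def make_estimator(cfg: EnsembleGraphConfig, p: int):
    """Construct the (unfitted) scikit-learn-style ensemble estimator."""
    n_trees = cfg.resolve_n_trees(p)
    if cfg.ensemble_kind == "boosted":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=n_trees,
            max_depth=cfg.max_depth,
            learning_rate=cfg.learning_rate,
            reg_lambda=cfg.reg_lambda,
            objective="binary:logistic",
            tree_method="exact",
            n_jobs=1,
            random_state=cfg.seed,
        )
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=n_trees, random_state=cfg.seed, n_jobs=1
    )


def _parse_xgboost(booster) -> list[DecisionTreeStructure]:
    df = booster.trees_to_dataframe()
    trees: list[DecisionTreeStructure] = []
    for _, tdf in df.groupby("Tree", sort=True):
        id_to_local = {nid: int(nid.split("-")[1]) for nid in tdf["ID"]}
        nodes: dict[int, TreeNode] = {}
        for row in tdf.itertuples(index=False):
            local = id_to_local[row.ID]
            if row.Feature == "Leaf":
                nodes[local] = TreeNode(local, is_leaf=True)
            else:
                nodes[local] = TreeNode(
                    local,
                    is_leaf=False,
                    split_feature_index=int(str(row.Feature).lstrip("f")),
                    left_child=id_to_local[row.Yes],
                    right_child=id_to_local[row.No],
                )
        trees.append(DecisionTreeStructure(nodes))
    return trees


def _parse_sklearn_tree(tree) -> DecisionTreeStructure:
    left, right, feat = tree.children_left, tree.children_right, tree.feature
    nodes = {}
    for i in range(tree.node_count):
        if left[i] == -1:  # leaf
            nodes[i] = TreeNode(i, is_leaf=True)
        else:
            nodes[i] = TreeNode(
                i,
                is_leaf=False,
                split_feature_index=int(feat[i]),
                left_child=int(left[i]),
                right_child=int(right[i]),
            )
    return DecisionTreeStructure(nodes)


def parse_fitted_ensemble(estimator, kind: str) -> list[DecisionTreeStructure]:
    """Parse every tree of a fitted estimator into plain structures."""
    if kind == "boosted":
        return _parse_xgboost(estimator.get_booster())
    return [_parse_sklearn_tree(e.tree_) for e in estimator.estimators_]


def fit_ensemble(
    train: ExpressionDataset, cfg: EnsembleGraphConfig
) -> list[DecisionTreeStructure]:
    """Fit the ensemble on the training data and return parsed tree structures."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training labels contain a single class")
    est = make_estimator(cfg, train.p)
    est.fit(train.X, train.y)
    return parse_fitted_ensemble(est, cfg.ensemble_kind)


def extract_tree_graph(tree: DecisionTreeStructure, p: int) -> FeatureGraph:
    """Directed graph of one tree: parent-split → child-split feature edges.

    Returned over the full ``p``-feature label space (features the tree never
    splits on are isolated).  Self-pairs (parent and child split on the same
    feature) are dropped here; self-loops are added globally when the mask is
    built.  Leaf content never matters.
    """
    labels = [f"f{j}" for j in range(p)]
    edges: set[tuple[int, int]] = set()
    for node in tree.internal_nodes():
        f = node.split_feature_index
        if f is None or f >= p:
            raise ValueError(f"split feature index {f} out of range for p={p}")
        for child_id in (node.left_child, node.right_child):
            child = tree.nodes[child_id]
            if child.is_leaf:
                continue
            f_child = child.split_feature_index
            if f_child >= p:
                raise ValueError(
                    f"split feature index {f_child} out of range for p={p}"
                )
            if f_child != f:
                edges.add((f, f_child))
    return FeatureGraph(labels, edges, directed=True)


def build_generated_graph(
    train: ExpressionDataset, cfg: EnsembleGraphConfig
) -> FeatureGraph:
    """Fit the ensemble and union the per-tree graphs into ``Gg``.

    ``Gg`` always has exactly ``p`` nodes; features never selected by any tree
    remain isolated (they still receive a self-loop in the adjacency mask).
    Bit-reproducible for fixed data and seed.
    """
    trees = fit_ensemble(train, cfg)
    graphs = [extract_tree_graph(t, train.p) for t in trees]
    if not graphs:
        return FeatureGraph([f"f{j}" for j in range(train.p)], (), directed=True)
    return union_graphs(graphs)
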