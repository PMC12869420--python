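"""Synthetic omics benchmark generator.

Emulates the structure of real expression data coupled to a biological
network: a scale-free Barabási–Albert graph plays the role of the external
feature graph, features are drawn from a multivariate normal whose covariance
is induced by the graph through a triangular structural-equation model, and a
binary outcome is produced by a nonlinear threshold on a sparse set of
informative features chosen preferentially among high-centrality nodes (with
one-hop expansion, mimicking the way disease genes cluster around network
hubs).

The generating pipeline, in order:

1. ``generate_ba_graph`` — undirected scale-free graph on ``p`` nodes.
2. ``build_covariance`` — each edge receives a Uniform[0.1, 10] weight in the
   weighted adjacency ``A*``; ``Σ_X = (I − A*)⁻¹ Σ_ε (I − A*)⁻ᵀ`` with
   ``Σ_ε = I``.  By default ``A*`` is symmetric (the weighted version of the
   undirected adjacency), which spreads outcome signal over many correlated
   features; an alternative strictly-upper-triangular orientation is provided
   (``orientation='triangular'``) but its multiplicative weight chains
   concentrate nearly all variance in a handful of features, collapsing the
   classification task to a trivially separable one.
3. ``sample_features`` — ``X ~ MVN(μ_X, Σ_X)`` with ``μ_X ~ Uniform[7, 13]``
   per feature.
4. ``select_true_features`` — seed features drawn 80%/20% from the top/bottom
   halves of the closeness-centrality ranking, then one-hop expanded.
5. ``generate_outcome`` — ``y_i = I(g(φ(η_i))`` above threshold``)`` with
   ``η = β0 + x_imp·β``, ``φ`` the min-max transform and
   ``g(φ) = exp(φ) + φ²``.

Thresholding note: ``g`` maps [0,1] into [1, e+1], so a literal comparison
``g > 0.6`` would be vacuous.  The default repair treats ``s`` as a quantile
level: a sample is positive iff its ``g`` value exceeds the empirical
``s``-quantile of ``g``, giving a fixed positive-class fraction of ``1 − s``
(0.4 at the default ``s = 0.6`` — mild class imbalance).  An alternative
repair that min-max rescales ``g`` to [0,1] before comparing with ``s`` is
available as ``threshold_mode='rescaled'``; it produces far stronger imbalance
(only the extreme upper tail of ``η`` is labelled positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from .data import ExpressionDataset
from .graph import FeatureGraph

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "generate_ba_graph",
    "build_covariance",
    "sample_features",
    "select_true_features",
    "generate_outcome",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow the benchmark design: n = 5000 samples, threshold
    s = 0.6 (positive fraction 0.4 under the quantile rule), edge weights
    Uniform[0.1, 10], feature means Uniform[7, 13], effect sizes
    Uniform[−5, 5], intercept N(−5, 5²), seed features drawn 80% from the
    high-centrality half of the graph.
    """

    p: int = 250
    n: int = 5000
    pt: float = 0.1
    s: float = 0.6
    ba_attachment: int = 1
    weight_range: tuple[float, float] = (0.1, 10.0)
    mu_x_range: tuple[float, float] = (7.0, 13.0)
    beta_range: tuple[float, float] = (-5.0, 5.0)
    beta0_mean: float = -5.0
    beta0_sd: float = 5.0
    high_centrality_fraction: float = 0.5
    hc_sampling_fraction: float = 0.8
    threshold_mode: str = "quantile"  # or "rescaled"
    orientation: str = "symmetric"  # or "triangular"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 3:
            raise ValueError("p must be at least 3")
        if not 0 < self.pt < 1:
            raise ValueError("pt must be in (0, 1)")
        if not 0 <= self.s < 1:
            raise ValueError("s must be in [0, 1)")
        if self.threshold_mode not in ("quantile", "rescaled"):
            raise ValueError("threshold_mode must be 'quantile' or 'rescaled'")
        if self.orientation not in ("symmetric", "triangular"):
            raise ValueError("orientation must be 'symmetric' or 'triangular'")


@dataclass
class SimulatedDataset:
    """A simulated dataset plus everything needed to evaluate against truth."""

    data: ExpressionDataset
    graph: FeatureGraph
    true_feature_mask: np.ndarray
    generating_params: dict[str, Any] = field(default_factory=dict)


def generate_ba_graph(p: int, m: int = 1, seed: int | None = None) -> FeatureGraph:
    """Undirected scale-free graph on ``p`` nodes via preferential attachment."""
    if not 1 <= m < p:
        raise ValueError(f"attachment parameter m={m} must satisfy 1 <= m < p={p}")
    g = nx.barabasi_albert_graph(p, m, seed=seed)
    labels = [f"f{j}" for j in range(p)]
    return FeatureGraph(labels, g.edges(), directed=False)


def build_covariance(
    graph: FeatureGraph,
    weight_range: tuple[float, float] = (0.1, 10.0),
    seed: int | None = None,
    orientation: str = "symmetric",
) -> tuple[np.ndarray, np.ndarray]:
    """Graph-induced SEM covariance ``Σ_X = (I − A*)⁻¹ Σ_ε (I − A*)⁻ᵀ``.

    Each undirected edge receives one Uniform[weight_range] weight.  Under the
    default ``orientation='symmetric'`` the weight occupies both ``(u, v)``
    and ``(v, u)`` — ``A*`` is the weighted version of the undirected
    adjacency — and ``Σ_X = (I − A*)⁻²`` is positive definite whenever
    ``I − A*`` is invertible (generic for random weights).  Under
    ``'triangular'`` the weight occupies only the strictly-upper-triangular
    position (lower → higher index), making ``I − A*`` unit triangular and
    always invertible, at the cost of multiplicative weight chains that let a
    few features dominate the total variance.  ``Σ_ε`` is the identity.
    Returns ``(A*, Σ_X)``.
    """
    if orientation not in ("symmetric", "triangular"):
        raise ValueError("orientation must be 'symmetric' or 'triangular'")
    rng = np.random.default_rng(seed)
    p = graph.p
    a_star = np.zeros((p, p))
    for u, v in sorted(graph.edges):
        lo, hi = (u, v) if u < v else (v, u)
        w = rng.uniform(*weight_range)
        a_star[lo, hi] = w
        if orientation == "symmetric":
            a_star[hi, lo] = w
    b = _sem_factor(a_star)
    sigma_x = b @ b.T
    return a_star, sigma_x


def _sem_factor(a_star: np.ndarray) -> np.ndarray:
    """``B = (I − A*)⁻¹`` such that ``Σ_X = B Bᵀ``."""
    m = np.eye(a_star.shape[0]) - a_star
    try:
        return np.linalg.inv(m)
    except np.linalg.LinAlgError as exc:
        raise ValueError("I - A* is singular; redraw the edge weights") from exc


def sample_features(
    n: int,
    sigma_x: np.ndarray | None,
    mu_x_range: tuple[float, float] = (7.0, 13.0),
    seed: int | None = None,
    factor: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n`` rows from ``MVN(μ_X, Σ_X)`` with per-feature uniform means.

    If ``factor`` (a matrix ``B`` with ``Σ_X = B Bᵀ``, e.g. the unit-triangular
    SEM factor) is given, it is used directly — numerically safer than
    factorising ``Σ_X``, whose condition number explodes for long weighted
    paths.  Otherwise ``Σ_X`` is factorised by Cholesky (must be positive
    definite).
    """
    rng = np.random.default_rng(seed)
    if factor is None:
        if sigma_x is None:
            raise ValueError("provide sigma_x or factor")
        sigma_x = np.asarray(sigma_x)
        try:
            factor = np.linalg.cholesky(sigma_x)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance matrix is not positive definite") from exc
    p = factor.shape[0]
    mu = rng.uniform(*mu_x_range, size=p)
    z = rng.standard_normal((n, p))
    return mu + z @ factor.T


def select_true_features(
    graph: FeatureGraph,
    pt: float,
    high_centrality_fraction: float = 0.5,
    hc_sampling_fraction: float = 0.8,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick seed features stratified by closeness centrality, then expand.

    Nodes are ranked by closeness centrality; the top
    ``high_centrality_fraction`` form the high-centrality group Hc and the rest
    Lc.  ``round(pt·p)`` seeds are drawn without replacement,
    ``hc_sampling_fraction`` of them from Hc.  The returned mask marks seeds
    plus all their one-hop neighbours (the informative set ``X_imp``).
    Centrality ties are broken by node index for determinism.
    """
    p = graph.p
    n_seeds = int(np.floor(pt * p + 0.5))
    if n_seeds < 1:
        raise ValueError(f"pt*p = {pt * p:.3g} selects no seed features")
    rng = np.random.default_rng(seed)
    nxg = nx.Graph()
    nxg.add_nodes_from(range(p))
    nxg.add_edges_from(graph.edges)
    closeness = nx.closeness_centrality(nxg)
    # sort: centrality descending, index ascending on ties
    order = sorted(range(p), key=lambda j: (-closeness[j], j))
    n_hc = int(high_centrality_fraction * p)
    hc, lc = order[:n_hc], order[n_hc:]
    n_from_hc = min(int(np.floor(hc_sampling_fraction * n_seeds + 0.5)), len(hc))
    n_from_lc = min(n_seeds - n_from_hc, len(lc))
    seeds = np.concatenate(
        [
            rng.choice(hc, size=n_from_hc, replace=False),
            rng.choice(lc, size=n_from_lc, replace=False),
        ]
    ).astype(int)
    mask = np.zeros(p, dtype=int)
    mask[seeds] = 1
    # one-hop expansion: neighbours of seeds (graph is undirected)
    seed_set = set(seeds.tolist())
    for u, v in graph.edges:
        if u in seed_set:
            mask[v] = 1
        if v in seed_set:
            mask[u] = 1
    return np.sort(seeds), mask


def _minmax(v: np.ndarray) -> np.ndarray:
    rng_ = v.max() - v.min()
    if rng_ == 0:
        return np.zeros_like(v)
    return (v - v.min()) / rng_


def generate_outcome(
    X: np.ndarray,
    expanded_mask: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    s: float = 0.6,
    threshold_mode: str = "quantile",
) -> np.ndarray:
    """Binary labels from the nonlinear thresholded linear predictor.

    ``η_i = β0 + x_i[imp]·β``; ``φ`` min-max rescales ``η`` to [0,1];
    ``g = exp(φ) + φ²``.  Under ``threshold_mode='quantile'`` (default) a
    sample is positive iff ``g_i`` exceeds the empirical ``s``-quantile of
    ``g`` (positive fraction ``1 − s``); under ``'rescaled'``, ``g`` is itself
    min-max rescaled to [0,1] and compared with ``s`` directly.  Both rules are
    monotone in ``η``: the max-η sample is always positive and the min-η sample
    always negative (for ``s > 0``).
    """
    imp = np.flatnonzero(np.asarray(expanded_mask))
    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape != (imp.size,):
        raise ValueError(f"beta has shape {beta.shape}, expected ({imp.size},)")
    eta = beta0 + X[:, imp] @ beta
    phi = _minmax(eta)
    g = np.exp(phi) + phi**2
    if threshold_mode == "quantile":
        thr = np.quantile(g, s)
    elif threshold_mode == "rescaled":
        thr = g.min() + s * (g.max() - g.min())
    else:
        raise ValueError("threshold_mode must be 'quantile' or 'rescaled'")
    return (g > thr).astype(np.int64)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the full generating pipeline under one configuration.

    All randomness derives from ``cfg.seed``; the drawn parameters (β0, β,
    seed features, μ_X) are recorded in ``generating_params`` for provenance.
    Degenerate single-class outcomes trigger a bounded β resample.
    """
    root = np.random.default_rng(cfg.seed)
    sub = root.integers(0, 2**31 - 1, size=5)
    graph = generate_ba_graph(cfg.p, cfg.ba_attachment, seed=int(sub[0]))
    a_star, _ = build_covariance(
        graph, cfg.weight_range, seed=int(sub[1]), orientation=cfg.orientation
    )
    X = sample_features(
        cfg.n, None, cfg.mu_x_range, seed=int(sub[2]), factor=_sem_factor(a_star)
    )
    seeds, mask = select_true_features(
        graph,
        cfg.pt,
        cfg.high_centrality_fraction,
        cfg.hc_sampling_fraction,
        seed=int(sub[3]),
    )
    rng = np.random.default_rng(int(sub[4]))
    n_imp = int(mask.sum())
    for _ in range(20):
        beta0 = rng.normal(cfg.beta0_mean, cfg.beta0_sd)
        beta = rng.uniform(*cfg.beta_range, size=n_imp)
        y = generate_outcome(X, mask, beta0, beta, cfg.s, cfg.threshold_mode)
        if 0 < y.sum() < cfg.n:
            break
    else:
        raise RuntimeError("could not generate a two-class outcome; check config")
    data = ExpressionDataset(X, y, feature_names=list(graph.node_labels))
    return SimulatedDataset(
        data=data,
        graph=graph,
        true_feature_mask=mask,
        generating_params={
            "beta0": float(beta0),
            "beta": beta,
            "seed_features": seeds,
            "config": cfg,
        },
    )
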