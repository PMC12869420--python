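"""Graph-embedded feedforward networks, implemented in NumPy.

The graph-embedded deep feedforward network (GEDFN) is a multilayer
perceptron whose input → first-hidden connections are restricted to a feature
graph: the first transformation is ``H1 = σ(X (W ⊙ Ã) + b)`` where ``Ã`` is
the self-loop-augmented adjacency matrix acting as a structural mask on the
weights.  Hidden unit ``u`` therefore aggregates only feature ``u`` itself and
its graph neighbours (``Ã_ju = 1``); subsequent layers are ordinary dense
layers.

The mask is applied multiplicatively at every forward pass (never by one-time
zeroing), so both the output and the gradient of any weight outside the graph
support are identically zero — an exactly testable invariant.

Two network shapes are provided:

* :class:`GEDFNNetwork` — one masked branch ``[p, 64, 16]`` with a
  ``16 → 2`` softmax head (the single-graph models; with an all-ones mask it
  degenerates to the plain DFN baseline).
* :class:`EngGNNNetwork` — two masked branches (external graph, generated
  graph) whose 16-wide embeddings are concatenated and passed through a
  one-hidden-layer (width 16) fusion network with a softmax output.

Training uses Adam with mini-batches, categorical cross-entropy, inverted
dropout on the fully-connected hidden layers (never on the masked layer), and
early stopping on a validation split carved from the training data, restoring
the best-epoch weights.  All randomness flows from a single seeded generator,
so fits are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import AdjacencyMatrix

__all__ = [
    "TrainingConfig",
    "masked_dense_forward",
    "cross_entropy_loss",
    "relu",
    "GEDFNNetwork",
    "EngGNNNetwork",
    "train_network",
]

EMBED_WIDTH = 16
HIDDEN_WIDTH = 64
FUSION_HIDDEN = 16
N_CLASSES = 2


@dataclass
class TrainingConfig:
    """Optimizer and regularization settings shared by all networks."""

    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 16
    dropout_rate: float = 0.2
    early_stopping_patience: int = 5
    validation_fraction: float = 0.1
    monitor: str = "val"  # or "train"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("epochs", "batch_size", "early_stopping_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.monitor not in ("val", "train"):
            raise ValueError("monitor must be 'val' or 'train'")


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def masked_dense_forward(X, W, b, mask, activation=relu) -> np.ndarray:
    """``activation(X (W ⊙ Ã) + b)`` — the graph-embedded first layer.

    ``mask`` may be an :class:`AdjacencyMatrix` or a raw 0/1 array.  Weights
    where the mask is zero have no effect on the output.
    """
    m = mask.values if isinstance(mask, AdjacencyMatrix) else np.asarray(mask)
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if X.shape[1] != W.shape[0] or W.shape != m.shape:
        raise ValueError(
            f"dimension mismatch: X {X.shape}, W {W.shape}, mask {m.shape}"
        )
    z = X @ (W * m) + b
    return activation(z) if activation is not None else z


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(y_onehot: np.ndarray, class_probs: np.ndarray) -> float:
    """Mean categorical cross-entropy ``−Σ_k y_k ln p_k`` over the batch."""
    p = np.asarray(class_probs, dtype=np.float64)
    y = np.asarray(y_onehot, dtype=np.float64)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("class probabilities must lie in [0, 1]")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("class probability rows must sum to 1")
    return float(-(y * np.log(np.clip(p, 1e-12, 1.0))).sum(axis=1).mean())


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)


def _as_mask_array(mask) -> np.ndarray:
    m = mask.values if isinstance(mask, AdjacencyMatrix) else np.asarray(mask)
    if not isinstance(mask, AdjacencyMatrix) or not mask.self_loops:
        # callers normally pass Ã; tolerate raw arrays with unit diagonal
        if not (np.diag(m) == 1).all():
            raise ValueError("mask must have a unit diagonal (Ã = A + I form)")
    return np.asarray(m, dtype=np.float64)


def _dropout_mask(rng, shape, rate):
    keep = 1.0 - rate
    return (rng.uniform(size=shape) < keep) / keep


def _branch_init(params, prefix, p, rng):
    params[f"{prefix}.W1"] = _he_init(rng, p, p)
    params[f"{prefix}.b1"] = np.zeros(p)
    params[f"{prefix}.W2"] = _he_init(rng, p, HIDDEN_WIDTH)
    params[f"{prefix}.b2"] = np.zeros(HIDDEN_WIDTH)
    params[f"{prefix}.W3"] = _he_init(rng, HIDDEN_WIDTH, EMBED_WIDTH)
    params[f"{prefix}.b3"] = np.zeros(EMBED_WIDTH)


def _branch_forward(params, prefix, mask, X, rate, train, rng, cache):
    z1 = X @ (params[f"{prefix}.W1"] * mask) + params[f"{prefix}.b1"]
    h1 = relu(z1)
    z2 = h1 @ params[f"{prefix}.W2"] + params[f"{prefix}.b2"]
    h2 = relu(z2)
    d2 = _dropout_mask(rng, h2.shape, rate) if train and rate > 0 else 1.0
    h2d = h2 * d2
    z3 = h2d @ params[f"{prefix}.W3"] + params[f"{prefix}.b3"]
    h3 = relu(z3)
    d3 = _dropout_mask(rng, h3.shape, rate) if train and rate > 0 else 1.0
    out = h3 * d3
    cache[prefix] = (X, z1, h1, z2, d2, h2d, z3, d3)
    return out


def _branch_backward(params, prefix, mask, cache, d_out, grads):
    X, z1, h1, z2, d2, h2d, z3, d3 = cache[prefix]
    dh3 = d_out * d3
    dz3 = dh3 * (z3 > 0)
    grads[f"{prefix}.W3"] = h2d.T @ dz3
    grads[f"{prefix}.b3"] = dz3.sum(axis=0)
    dh2d = dz3 @ params[f"{prefix}.W3"].T
    dh2 = dh2d * d2
    dz2 = dh2 * (z2 > 0)
    grads[f"{prefix}.W2"] = h1.T @ dz2
    grads[f"{prefix}.b2"] = dz2.sum(axis=0)
    dh1 = dz2 @ params[f"{prefix}.W2"].T
    dz1 = dh1 * (z1 > 0)
    # chain rule through W ⊙ Ã: gradients outside the support are exactly zero
    grads[f"{prefix}.W1"] = (X.T @ dz1) * mask
    grads[f"{prefix}.b1"] = dz1.sum(axis=0)


class GEDFNNetwork:
    """Single-branch GEDFN classifier: masked ``[p, 64, 16]`` + 16→2 head.

    With an all-ones mask this is the plain deep feedforward network (DFN)
    baseline — identical widths, fully connected first layer.
    """

    def __init__(self, mask) -> None:
        self.mask = _as_mask_array(mask)
        self.p = self.mask.shape[0]

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        _branch_init(params, "b0", self.p, rng)
        params["head.W"] = _he_init(rng, EMBED_WIDTH, N_CLASSES)
        params["head.b"] = np.zeros(N_CLASSES)
        return params

    def forward(self, params, X, train=False, rng=None, rate=0.0):
        cache: dict = {}
        out = _branch_forward(params, "b0", self.mask, X, rate, train, rng, cache)
        logits = out @ params["head.W"] + params["head.b"]
        probs = _softmax(logits)
        cache["head_in"] = out
        cache["probs"] = probs
        return probs, cache

    def backward(self, params, cache, y_onehot):
        grads: dict[str, np.ndarray] = {}
        batch = y_onehot.shape[0]
        dlogits = (cache["probs"] - y_onehot) / batch
        grads["head.W"] = cache["head_in"].T @ dlogits
        grads["head.b"] = dlogits.sum(axis=0)
        d_out = dlogits @ params["head.W"].T
        _branch_backward(params, "b0", self.mask, cache, d_out, grads)
        return grads

    def embed(self, params, X) -> np.ndarray:
        """Evaluation-mode 16-wide embedding (the last hidden layer)."""
        cache: dict = {}
        return _branch_forward(params, "b0", self.mask, X, 0.0, False, None, cache)

    def input_weights(self, params) -> np.ndarray:
        return params["b0.W1"]


class EngGNNNetwork:
    """Dual-branch network: GEDFN(Ge) ‖ GEDFN(Gg) → fusion DFN → softmax.

    The two 16-wide branch embeddings are concatenated into a 32-wide
    representation and passed through one fully-connected hidden layer of
    width 16 before the 2-class softmax output.  Both branches and the head
    are trained jointly under a single cross-entropy loss.
    """

    def __init__(self, mask_e, mask_g) -> None:
        self.mask_e = _as_mask_array(mask_e)
        self.mask_g = _as_mask_array(mask_g)
        if self.mask_e.shape != self.mask_g.shape:
            raise ValueError("the two branch masks must share the feature space")
        self.p = self.mask_e.shape[0]

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        _branch_init(params, "e", self.p, rng)
        _branch_init(params, "g", self.p, rng)
        params["fuse.W"] = _he_init(rng, 2 * EMBED_WIDTH, FUSION_HIDDEN)
        params["fuse.b"] = np.zeros(FUSION_HIDDEN)
        params["head.W"] = _he_init(rng, FUSION_HIDDEN, N_CLASSES)
        params["head.b"] = np.zeros(N_CLASSES)
        return params

    def forward(self, params, X, train=False, rng=None, rate=0.0):
        cache: dict = {}
        out_e = _branch_forward(params, "e", self.mask_e, X, rate, train, rng, cache)
        out_g = _branch_forward(params, "g", self.mask_g, X, rate, train, rng, cache)
        hc = np.concatenate([out_e, out_g], axis=1)
        zf = hc @ params["fuse.W"] + params["fuse.b"]
        hf = relu(zf)
        df = _dropout_mask(rng, hf.shape, rate) if train and rate > 0 else 1.0
        hfd = hf * df
        logits = hfd @ params["head.W"] + params["head.b"]
        probs = _softmax(logits)
        cache.update(hc=hc, zf=zf, df=df, hfd=hfd, probs=probs)
        return probs, cache

    def backward(self, params, cache, y_onehot):
        grads: dict[str, np.ndarray] = {}
        batch = y_onehot.shape[0]
        dlogits = (cache["probs"] - y_onehot) / batch
        grads["head.W"] = cache["hfd"].T @ dlogits
        grads["head.b"] = dlogits.sum(axis=0)
        dhfd = dlogits @ params["head.W"].T
        dhf = dhfd * cache["df"]
        dzf = dhf * (cache["zf"] > 0)
        grads["fuse.W"] = cache["hc"].T @ dzf
        grads["fuse.b"] = dzf.sum(axis=0)
        dhc = dzf @ params["fuse.W"].T
        _branch_backward(params, "e", self.mask_e, cache, dhc[:, :EMBED_WIDTH], grads)
        _branch_backward(params, "g", self.mask_g, cache, dhc[:, EMBED_WIDTH:], grads)
        return grads

    def embed(self, params, X) -> np.ndarray:
        """Evaluation-mode concatenated 32-wide representation ``HC``."""
        cache: dict = {}
        out_e = _branch_forward(params, "e", self.mask_e, X, 0.0, False, None, cache)
        out_g = _branch_forward(params, "g", self.mask_g, X, 0.0, False, None, cache)
        return np.concatenate([out_e, out_g], axis=1)


def _stratified_holdout(y, fraction, rng):
    """Indices (train, val) with ~fraction per class held out."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = int(np.floor(fraction * idx.size))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def train_network(net, X, y, config: TrainingConfig):
    """Mini-batch Adam training with early stopping.

    Returns ``(params, trace)`` where ``params`` are the weights restored at
    the best monitored epoch and ``trace`` is the per-epoch monitored loss.
    Raises on a non-finite loss.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    params = net.init_params(rng)
    eye = np.eye(N_CLASSES)

    if config.monitor == "val":
        fit_idx, val_idx = _stratified_holdout(y, config.validation_fraction, rng)
        if val_idx.size == 0 or len(np.unique(y[val_idx])) < 1:
            fit_idx = np.arange(X.shape[0])
            val_idx = None
    else:
        fit_idx, val_idx = np.arange(X.shape[0]), None
    X_fit, y_fit = X[fit_idx], y[fit_idx]
    X_mon = X[val_idx] if val_idx is not None else X_fit
    y_mon = y[val_idx] if val_idx is not None else y_fit

    keys = sorted(params)
    m = {k: np.zeros_like(params[k]) for k in keys}
    v = {k: np.zeros_like(params[k]) for k in keys}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_loss = np.inf
    best_params = {k: params[k].copy() for k in keys}
    bad_epochs = 0
    trace: list[float] = []

    n_fit = X_fit.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n_fit)
        for start in range(0, n_fit, config.batch_size):
            batch = order[start : start + config.batch_size]
            probs, cache = net.forward(
                params, X_fit[batch], train=True, rng=rng, rate=config.dropout_rate
            )
            if not np.isfinite(probs).all():
                raise FloatingPointError("non-finite network output during training")
            grads = net.backward(params, cache, eye[y_fit[batch]])
            step += 1
            corr = np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k in keys:
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                params[k] -= config.learning_rate * corr * m[k] / (np.sqrt(v[k]) + eps)
        probs_mon, _ = net.forward(params, X_mon, train=False)
        loss = cross_entropy_loss(eye[y_mon], probs_mon)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite monitored loss")
        trace.append(loss)
        if loss < best_loss - 1e-12:
            best_loss = loss
            best_params = {k: params[k].copy() for k in keys}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stopping_patience:
                break
    return best_params, trace
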