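"""Connection-weight feature importance and percentile-rank pseudo-probabilities.

The importance of feature ``j`` in one GEDFN branch is the sum of the masked
first-layer weights in which ``j`` participates — its row (outgoing
connections of input ``j``) plus its column (connections into hidden unit
``j``)::

    IF_j = Σ_u W_ju · I(Ã_ju = 1)  +  Σ_v W_vj · I(Ã_vj = 1)

For the dual-graph model the score is the sum of the two branch components,
``IF_j = IF_j(Ge) + IF_j(Gg)``.  By default the *magnitudes* of the weights
are summed (``use_abs=True``): a feature is influential whether its
first-layer weights are positive or negative, and signed sums over many
masked connections cancel towards zero, destroying the ranking.  The raw
signed variant (``use_abs=False``) is retained for analyses that care about
the net direction of a feature's first-layer contribution.

Scores from different models are made comparable by the percentile-rank
transform (empirical CDF): ``rank_j = #{k : score_k ≤ score_j} / p``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .graph import AdjacencyMatrix

__all__ = [
    "connection_weight_scores",
    "enggnn_importance",
    "percentile_ranks",
]


def connection_weight_scores(W, mask, use_abs: bool = True) -> np.ndarray:
    """Masked row-sum plus masked column-sum of the first-layer weights.

    ``W`` is the ``p × p`` input → first-hidden weight matrix of one branch
    and ``mask`` its self-loop-augmented adjacency ``Ã``.  An isolated feature
    (self-loop only) scores ``2·|W_jj|`` (``2·W_jj`` with ``use_abs=False``).
    """
    m = mask.values if isinstance(mask, AdjacencyMatrix) else np.asarray(mask)
    W = np.asarray(W, dtype=np.float64)
    if W.shape != m.shape or W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"shape mismatch: W {W.shape} vs mask {m.shape}")
    effective = (np.abs(W) if use_abs else W) * (m != 0)
    return effective.sum(axis=1) + effective.sum(axis=0)


def percentile_ranks(scores: np.ndarray) -> np.ndarray:
    """Empirical-CDF pseudo-probabilities: ``(#scores ≤ score_j) / p``.

    Ties share the same (maximal) rank; the transform is order-preserving and
    the largest score always maps to 1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("importance scores must be finite")
    return rankdata(scores, method="max") / scores.size


def enggnn_importance(model, use_abs: bool = True) -> pd.DataFrame:
    """Connection-weight importance table for a fitted network model.

    Works for the dual-graph model and for any single-branch GEDFN/DFN
    baseline exposing ``input_weights()`` (the absent branch component is
    zero; the DFN uses its all-ones mask).  Columns: ``feature``, ``if_ge``,
    ``if_gg``, ``if_total``, ``percentile_rank``, ``rank_order`` (1 = most
    important).
    """
    branches = model.input_weights()
    some_w, _ = next(iter(branches.values()))
    p = some_w.shape[0]
    if_ge = np.zeros(p)
    if_gg = np.zeros(p)
    if "ge" in branches:
        if_ge = connection_weight_scores(*branches["ge"], use_abs=use_abs)
    if "gg" in branches:
        if_gg = connection_weight_scores(*branches["gg"], use_abs=use_abs)
    total = if_ge + if_gg
    ranks = percentile_ranks(total)
    order = np.empty(p, dtype=int)
    order[np.argsort(-total, kind="stable")] = np.arange(1, p + 1)
    return pd.DataFrame(
        {
            "feature": list(model.feature_names) or [f"f{j}" for j in range(p)],
            "if_ge": if_ge,
            "if_gg": if_gg,
            "if_total": total,
            "percentile_rank": ranks,
            "rank_order": order,
        }
    )
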