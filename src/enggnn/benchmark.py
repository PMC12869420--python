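"""Replicated simulation benchmark over the (pn, pt) scenario grid.

A scenario fixes the sample-to-feature ratio ``pn`` (so ``p = round(pn·n)``)
and the true-feature proportion ``pt``.  Per replicate ``r`` a dataset is
simulated with seed ``base_seed + r``, split 80/20 (stratified by class),
every requested model is fitted on the training split, and classification
metrics on the test split plus feature-selection metrics against the
simulator's ground truth are recorded.  The summary table reports mean and SD
per (model, metric) cell; failed fits are logged and marked, never silently
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .data import ExpressionDataset
from .importance import enggnn_importance, percentile_ranks
from .metrics import classification_metrics, feature_selection_metrics, welch_compare
from .model import BASELINE_KINDS, fit_baseline, fit_enggnn
from .nn import TrainingConfig
from .simulate import SimulationConfig, simulate_dataset
from .tree_graph import EnsembleGraphConfig

__all__ = [
    "ScenarioSpec",
    "SCENARIO_GRID",
    "run_scenario",
    "summarize_replicates",
    "compare_models",
    "tree_baseline_importance",
]

logger = logging.getLogger("enggnn.benchmark")

ALL_MODELS = ("enggnn",) + BASELINE_KINDS

#: The nine benchmark scenarios: pn × pt ∈ {0.05, 0.1, 0.2}².
SCENARIO_GRID = [(pn, pt) for pn in (0.05, 0.1, 0.2) for pt in (0.05, 0.1, 0.2)]


@dataclass
class ScenarioSpec:
    pn: float = 0.05
    pt: float = 0.1
    n: int = 5000
    replicates: int = 20
    train_fraction: float = 0.8
    models: tuple[str, ...] = ALL_MODELS
    base_seed: int = 0
    epochs: int = 50
    threshold_mode: str = "quantile"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown model kinds: {sorted(unknown)}")

    @property
    def p(self) -> int:
        return int(np.floor(self.pn * self.n + 0.5))


def tree_baseline_importance(model) -> np.ndarray:
    """Percentile-ranked native importance of a fitted tree baseline."""
    return percentile_ranks(model.native_importance())


def _model_importance_probs(kind: str, model) -> np.ndarray:
    if kind in ("boosted_trees", "random_forest"):
        return tree_baseline_importance(model)
    table = enggnn_importance(model)
    return table["percentile_rank"].to_numpy()


def _fit_one(kind, train, graph, train_cfg):
    if kind == "enggnn":
        return fit_enggnn(train, graph, train_config=train_cfg)
    return fit_baseline(kind, train, external_graph=graph, train_config=train_cfg)


def run_scenario(spec: ScenarioSpec) -> pd.DataFrame:
    """Run all replicates of one scenario; returns per-replicate records.

    Columns: replicate, model, accuracy, roc_auc, f1, fs_roc_auc, fs_pr_auc,
    failed.  Aggregate with :func:`summarize_replicates`.
    """
    records: list[dict] = []
    for r in range(spec.replicates):
        seed = spec.base_seed + r
        sim = simulate_dataset(
            SimulationConfig(
                p=spec.p,
                n=spec.n,
                pt=spec.pt,
                threshold_mode=spec.threshold_mode,
                seed=seed,
            )
        )
        idx_train, idx_test = train_test_split(
            np.arange(sim.data.n),
            test_size=1.0 - spec.train_fraction,
            stratify=sim.data.y,
            random_state=seed,
        )
        train, test = sim.data.subset(idx_train), sim.data.subset(idx_test)
        train_cfg = TrainingConfig(seed=seed, epochs=spec.epochs)
        for kind in spec.models:
            rec = {"replicate": r, "model": kind, "failed": False}
            try:
                model = _fit_one(kind, train, sim.graph, train_cfg)
                pred = model.predict(test.X)
                rep = classification_metrics(
                    test.y, pred.predicted_labels, pred.class_probs[:, 1]
                )
                fs_roc, fs_pr = feature_selection_metrics(
                    sim.true_feature_mask, _model_importance_probs(kind, model)
                )
                rec.update(
                    accuracy=rep.accuracy,
                    roc_auc=rep.roc_auc,
                    f1=rep.f1,
                    fs_roc_auc=fs_roc,
                    fs_pr_auc=fs_pr,
                )
                logger.info(
                    "scenario pn=%.2f pt=%.2f rep=%d model=%s acc=%.3f auc=%.3f",
                    spec.pn, spec.pt, r, kind, rep.accuracy, rep.roc_auc or np.nan,
                )
            except Exception:  # a failed fit is a recorded cell, not a crash
                logger.exception(
                    "model %s failed in replicate %d of pn=%.2f pt=%.2f",
                    kind, r, spec.pn, spec.pt,
                )
                rec["failed"] = True
            records.append(rec)
    df = pd.DataFrame(records)
    df.insert(0, "pt", spec.pt)
    df.insert(0, "pn", spec.pn)
    return df


METRIC_COLUMNS = ("accuracy", "roc_auc", "f1", "fs_roc_auc", "fs_pr_auc")


def summarize_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) per (pn, pt, model, metric) over successful replicates."""
    ok = per_replicate[~per_replicate["failed"]]
    rows = []
    for (pn, pt, model), grp in ok.groupby(["pn", "pt", "model"]):
        for metric in METRIC_COLUMNS:
            if metric not in grp:
                continue
            vals = grp[metric].dropna()
            rows.append(
                {
                    "metric": metric,
                    "pn": pn,
                    "pt": pt,
                    "model": model,
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    "n_replicates": len(vals),
                }
            )
    return pd.DataFrame(rows)


def compare_models(
    per_replicate: pd.DataFrame, model_a: str, model_b: str, metric: str = "accuracy"
) -> tuple[float, float]:
    """Welch's t-test between two models' per-replicate metric vectors."""
    ok = per_replicate[~per_replicate["failed"]]
    a = ok.loc[ok["model"] == model_a, metric].dropna().to_numpy()
    b = ok.loc[ok["model"] == model_b, metric].dropna().to_numpy()
    return welch_compare(a, b)
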