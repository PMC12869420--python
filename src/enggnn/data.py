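"""Expression datasets and Z-score normalization.

An :class:`ExpressionDataset` holds an ``n × p`` expression matrix ``X`` with
binary labels ``y``.  Feature names align positionally with
:class:`~enggnn.graph.FeatureGraph` node labels whenever a dataset and a graph
are used together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ZScoreStats",
    "zscore_normalize",
    "apply_zscore",
    "read_expression_matrix",
    "write_expression_matrix",
]

#: Floor applied to per-feature standard deviations so constant features map to 0.
SD_FLOOR = 1e-8


@dataclass
class ExpressionDataset:
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError(f"y has shape {self.y.shape}, expected ({n},)")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal p")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal n")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: Sequence[int]) -> "ExpressionDataset":
        rows = np.asarray(rows)
        return ExpressionDataset(
            self.X[rows],
            self.y[rows],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in rows],
        )


@dataclass(frozen=True)
class ZScoreStats:
    """Per-feature mean and (floored, population) standard deviation."""

    mean: np.ndarray
    sd: np.ndarray


def zscore_normalize(
    dataset: ExpressionDataset, stats_from: Sequence[int] | None = None
) -> tuple[ExpressionDataset, ZScoreStats]:
    """Z-score each feature column, returning the transformed data and stats.

    Statistics are computed on the rows in ``stats_from`` (default: all rows) so
    that training-split statistics can be reused on held-out rows via
    :func:`apply_zscore`.  The sd is the population sd (divide by n) with a
    floor of ``SD_FLOOR``, so constant columns transform to all zeros.
    """
    if stats_from is None:
        ref = dataset.X
    else:
        idx = np.asarray(stats_from)
        if idx.size == 0:
            raise ValueError("stats_from must select at least one row")
        ref = dataset.X[idx]
    mean = ref.mean(axis=0)
    sd = np.maximum(ref.std(axis=0), SD_FLOOR)
    stats = ZScoreStats(mean=mean, sd=sd)
    out = ExpressionDataset(
        apply_zscore(dataset.X, stats),
        dataset.y,
        feature_names=list(dataset.feature_names),
        sample_ids=list(dataset.sample_ids),
    )
    return out, stats


def apply_zscore(X: np.ndarray, stats: ZScoreStats) -> np.ndarray:
    """Apply previously computed normalization stats to new rows."""
    return (np.asarray(X, dtype=np.float64) - stats.mean) / stats.sd


def read_expression_matrix(
    path,
    label_column: str | None = None,
    labels_path=None,
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix (rows = samples, columns = features).

    The first column holds sample ids and the header row feature names.  Labels
    come either from a named column of the matrix file or from a separate
    single-column file (``labels_path``).
    """
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    if label_column is not None:
        y = df[label_column].to_numpy()
        df = df.drop(columns=[label_column])
    elif labels_path is not None:
        y = pd.read_csv(labels_path, header=None).to_numpy().ravel()
    else:
        raise ValueError("provide label_column or labels_path")
    return ExpressionDataset(
        df.to_numpy(dtype=np.float64),
        y,
        feature_names=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def write_expression_matrix(dataset: ExpressionDataset, path, labels_path=None) -> None:
    """Write the matrix as TSV (sample id column + feature header)."""
    df = pd.DataFrame(dataset.X, index=dataset.sample_ids, columns=dataset.feature_names)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    if labels_path is not None:
        pd.Series(dataset.y).to_csv(labels_path, index=False, header=False)
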