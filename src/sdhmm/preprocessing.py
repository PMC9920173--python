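"""Data conditioning for compositional HMM fitting.

The chain applied to raw sensor feature tables, in this order:

1. median imputation of missing entries (robust to outliers),
2. per-feature min-max scaling into [0, 1],
3. optional SMOTE oversampling of minority classes (labeled data only),
4. projection of each row onto the interior of the probability simplex.

SMOTE interpolates in the scaled [0, 1] feature box *before* simplex
projection, so synthetic rows project to valid simplex points.  Because
interpolation between non-adjacent time steps breaks sequence order,
balanced outputs should be treated as bags of observations for emission
fitting while transition statistics come from the original ordered runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .scaled_dirichlet import SIMPLEX_EPS

__all__ = [
    "FeatureTable",
    "read_table",
    "write_table",
    "impute_median",
    "minmax_scale",
    "to_simplex",
    "smote",
    "preprocess",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """An (n, D) feature matrix with optional labels and synthetic flags."""

    X: np.ndarray
    labels: np.ndarray | None = None
    synthetic: np.ndarray | None = None
    columns: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] < 2:
            raise ValueError("X must be an (n, D) matrix with D >= 2")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.X.shape[0],):
                raise ValueError("labels must align with rows of X")
        if self.synthetic is None:
            self.synthetic = np.zeros(self.X.shape[0], dtype=bool)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def read_table(path, label_column: str | None = None, sep: str | None = None) -> FeatureTable:
    """Read a delimited text table (comma or tab; blank or 'NaN' = missing)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in table")
        labels = df.pop(label_column).to_numpy(dtype=int)
    return FeatureTable(df.to_numpy(dtype=float), labels=labels, columns=list(df.columns))


def write_table(path, table: FeatureTable, label_column: str = "label", sep: str = ",") -> None:
    cols = table.columns or [f"f{i}" for i in range(table.dim)]
    df = pd.DataFrame(table.X, columns=cols)
    if table.labels is not None:
        df[label_column] = table.labels
    df.to_csv(path, sep=sep, index=False)


def impute_median(table: FeatureTable) -> FeatureTable:
    """Replace each missing entry by the median of its feature's observed values."""
    X = table.X.copy()
    missing = np.isnan(X)
    fully_missing = np.where(missing.all(axis=0))[0]
    if fully_missing.size:
        raise ValueError(f"feature column {int(fully_missing[0])} has no observed values")
    if missing.any():
        med = np.nanmedian(X, axis=0)
        X[missing] = np.broadcast_to(med, X.shape)[missing]
        logger.info("imputed %d missing entries with feature medians", int(missing.sum()))
    return replace(table, X=X)


def minmax_scale(table: FeatureTable) -> FeatureTable:
    """Scale each feature to [0, 1]; constant features map to 0.5."""
    X = table.X
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before scaling")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    const = span <= 0
    span = np.where(const, 1.0, span)
    Xs = (X - lo) / span
    if const.any():
        Xs[:, const] = 0.5
        logger.info("constant features mapped to 0.5: %s", np.where(const)[0].tolist())
    return replace(table, X=Xs)


def to_simplex(table: FeatureTable) -> FeatureTable:
    """Clamp entries to >= eps and normalize each row to sum to one."""
    X = table.X
    if np.isnan(X).any() or X.min() < 0 or X.max() > 1 + 1e-9:
        raise ValueError("to_simplex expects scaled values in [0, 1] with no missing entries")
    if (X.sum(axis=1) == 0).any():
        logger.warning("all-zero rows encountered; clamping lifts them to uniform")
    Xc = np.clip(X, SIMPLEX_EPS, None)
    return replace(table, X=Xc / Xc.sum(axis=1, keepdims=True))


def smote(table: FeatureTable, k_neighbors: int = 5, rng: np.random.Generator | None = None) -> FeatureTable:
    """Balance classes by interpolating synthetic minority samples.

    For every class below the majority count, synthetic rows are drawn as
    x_new = x_i + u (x_nn - x_i) with u ~ Uniform(0, 1) and x_nn one of the
    k nearest same-class neighbors (Euclidean), until all classes reach the
    majority count.  Original rows are preserved; synthetic rows are flagged.
    """
    if table.labels is None:
        raise ValueError("SMOTE requires class labels")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    classes, counts = np.unique(table.labels, return_counts=True)
    target = counts.max()
    new_rows, new_labels = [], []
    for cls, cnt in zip(classes, counts):
        if cnt == target:
            continue
        if cnt < 2:
            raise ValueError(f"class {int(cls)} has a single member; cannot interpolate")
        k = k_neighbors
        if k >= cnt:
            k = cnt - 1
            warnings.warn(f"k_neighbors reduced to {k} for class {int(cls)} (size {int(cnt)})")
        Xc = table.X[table.labels == cls]
        d = cdist(Xc, Xc)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1)[:, :k]
        need = target - cnt
        base = rng.integers(0, cnt, size=need)
        pick = nn[base, rng.integers(0, k, size=need)]
        u = rng.uniform(0.0, 1.0, size=(need, 1))
        new_rows.append(Xc[base] + u * (Xc[pick] - Xc[base]))
        new_labels.append(np.full(need, cls))
    if not new_rows:
        return table
    X = np.vstack([table.X] + new_rows)
    labels = np.concatenate([table.labels] + new_labels)
    synthetic = np.concatenate(
        [table.synthetic, np.ones(X.shape[0] - table.n, dtype=bool)]
    )
    logger.info("SMOTE added %d synthetic rows (target %d per class)", X.shape[0] - table.n, int(target))
    return FeatureTable(X, labels=labels, synthetic=synthetic, columns=table.columns)


def preprocess(
    table: FeatureTable,
    apply_smote: bool = False,
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
) -> FeatureTable:
    """Full conditioning chain: impute -> scale -> (smote) -> simplex."""
    logger.info("preprocessing chain: impute -> scale -> %ssimplex", "smote -> " if apply_smote else "")
    out = minmax_scale(impute_median(table))
    if apply_smote:
        out = smote(out, k_neighbors=k_neighbors, rng=rng)
    return to_simplex(out)
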