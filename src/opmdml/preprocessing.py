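"""Feature pipeline: one-hot encoding, standardization, SMOTE balancing.

The design matrix is a thin named wrapper over a dense numpy array; column
names follow the ``variable=level`` convention so downstream models
(Cox, nomogram, attention importances) can map coefficients back to
clinical levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort_schema import (
    DEFAULT_SCHEMA,
    CohortSchemaError,
    FeatureSchema,
    PatientRecord,
)

__all__ = [
    "DesignMatrix",
    "Standardizer",
    "one_hot_encode",
    "decode_one_hot",
    "fit_standardizer",
    "apply_standardizer",
    "smote_oversample",
]

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """An n x d real matrix with unique column names and row ids."""

    values: np.ndarray
    column_names: list[str]
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        if len(self.column_names) != d:
            raise ValueError("column_names length mismatch")
        if len(set(self.column_names)) != d:
            raise ValueError("column names must be unique")
        if len(self.row_ids) != n:
            raise ValueError("row_ids length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def one_hot_encode(
    records: Sequence[PatientRecord],
    schema: FeatureSchema = DEFAULT_SCHEMA,
    drop_reference: bool = False,
) -> DesignMatrix:
    """Encode categorical records as a 0/1 design matrix.

    With ``drop_reference=False`` every level gets a column (the encoding
    used by the neural models); with ``drop_reference=True`` each
    variable's reference level is dropped (the encoding used by Cox
    regression, ``sum(levels - 1)`` columns).
    """
    cols: list[tuple[str, str]] = []
    for v in schema.variables:
        for lv in schema.levels[v]:
            if drop_reference and lv == schema.reference[v]:
                continue
            cols.append((v, lv))
    names = [f"{v}={lv}" for v, lv in cols]
    X = np.zeros((len(records), len(cols)))
    for i, r in enumerate(records):
        r.validate(schema)
        for j, (v, lv) in enumerate(cols):
            if r.level(v) == lv:
                X[i, j] = 1.0
    return DesignMatrix(X, names, [r.id for r in records])


def decode_one_hot(
    X: DesignMatrix, schema: FeatureSchema = DEFAULT_SCHEMA
) -> list[dict[str, str]]:
    """Inverse of :func:`one_hot_encode`: per-row variable -> level maps.

    Works for both encodings; with reference-dropped input an all-zero
    block decodes to the reference level.
    """
    col_of = {name: j for j, name in enumerate(X.column_names)}
    out: list[dict[str, str]] = []
    for i in range(X.shape[0]):
        row: dict[str, str] = {}
        for v in schema.variables:
            chosen = schema.reference[v]
            for lv in schema.levels[v]:
                j = col_of.get(f"{v}={lv}")
                if j is not None and X.values[i, j] >= 0.5:
                    chosen = lv
                    break
            row[v] = chosen
        out.append(row)
    return out


@dataclass
class Standardizer:
    """Per-column mean/sd learned on training data.

    Zero-variance columns pass through unscaled (sd stored as 1)."""

    column_names: list[str]
    mean: np.ndarray
    sd: np.ndarray


def fit_standardizer(X_train: DesignMatrix) -> Standardizer:
    if X_train.shape[0] == 0:
        raise ValueError("cannot fit standardizer on an empty matrix")
    mu = X_train.values.mean(axis=0)
    sd = X_train.values.std(axis=0)
    zero = sd <= 0
    mu = np.where(zero, 0.0, mu)
    sd = np.where(zero, 1.0, sd)
    return Standardizer(list(X_train.column_names), mu, sd)


def apply_standardizer(s: Standardizer, X: DesignMatrix) -> DesignMatrix:
    if list(X.column_names) != list(s.column_names):
        raise CohortSchemaError("standardizer/matrix column mismatch")
    Z = (X.values - s.mean) / s.sd
    return DesignMatrix(Z, list(X.column_names), list(X.row_ids))


def smote_oversample(
    X: DesignMatrix,
    y: Sequence[int] | np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[DesignMatrix, np.ndarray]:
    """Synthetic minority over-sampling by k-NN interpolation.

    Each synthetic point is ``x_i + u * (x_z - x_i)`` for a uniformly
    chosen minority point ``x_i``, one of its ``k`` nearest minority
    neighbours ``x_z`` (Euclidean), and ``u ~ U(0, 1)``; originals are kept
    unchanged and synthetic rows carry the minority label. After the call
    the minority count equals ``round(target_ratio * majority count)``
    (never reduced below the original minority count).
    """
    y = np.asarray(y).astype(int)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_oversample requires exactly two classes present")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min = counts.min()
    n_maj = counts.max()
    if n_min < 2:
        raise ValueError("minority class must have at least 2 samples")
    if k >= n_min:
        logger.warning(
            "SMOTE k=%d >= minority count %d; reducing k to %d",
            k, n_min, n_min - 1,
        )
        k = n_min - 1

    target = int(round(target_ratio * n_maj))
    n_new = max(0, target - n_min)
    if n_new == 0:
        return X, y.copy()

    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(y == minority)
    M = X.values[min_idx]
    # pairwise distances within the minority class
    d2 = ((M[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]

    base = rng.integers(0, len(min_idx), size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    a = M[base]
    b = M[nn[base, pick]]
    synth = a + u[:, None] * (b - a)

    values = np.vstack([X.values, synth])
    row_ids = list(X.row_ids) + [f"smote{i:05d}" for i in range(n_new)]
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return DesignMatrix(values, list(X.column_names), row_ids), y_out
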