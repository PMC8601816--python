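"""Tabular preprocessing: label encoding, deduplication, min-max scaling, PCA.

Scaling maps each feature to (x - min)/(max - min) using statistics of the
rows the scaler was fitted on; values outside that range are deliberately not
clipped, so held-out rows may fall outside [0, 1].  PCA is computed by
eigendecomposition of the sample covariance (divisor n-1) with a fixed sign
convention so repeated fits are bit-identical.

Both transformers follow the scikit-learn estimator API (fit/transform,
``get_params``, fitted attributes with a trailing underscore) and compose
with sklearn pipelines, but their math is implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


@dataclass
class FeatureTable:
    """Numeric instance-by-feature matrix with aligned binary labels."""

    values: np.ndarray
    column_names: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one feature column")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal the number of rows")
        if len(self.column_names) != self.values.shape[1]:
            raise ValueError("column_names length must equal the number of columns")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(self.values[idx], list(self.column_names), self.labels[idx])

    def with_values(self, values, column_names=None) -> "FeatureTable":
        names = column_names if column_names is not None else list(self.column_names)
        return FeatureTable(values, names, self.labels.copy())


def encode_labels(raw_column) -> tuple[np.ndarray, dict]:
    """Map category tokens to consecutive integers 0..m-1.

    Categories are ordered lexicographically by token string, so the mapping
    is deterministic across runs.  Returns the integer codes and the
    token -> code mapping for round-tripping.
    """
    tokens = [str(t) for t in raw_column]
    if len(tokens) == 0:
        raise ValueError("cannot encode an empty column")
    mapping = {tok: i for i, tok in enumerate(sorted(set(tokens)))}
    return np.array([mapping[t] for t in tokens], dtype=int), mapping


def deduplicate(table: FeatureTable) -> FeatureTable:
    """Drop exact duplicate rows (identical features AND label), keeping the
    first occurrence and preserving row order.  Rows that share features but
    disagree on the label are not duplicates."""
    df = pd.DataFrame(table.values)
    df["__label__"] = table.labels
    keep = ~df.duplicated(keep="first").to_numpy()
    return table.subset(np.flatnonzero(keep))


class MinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-column (x - min)/(max - min) scaling fitted on training rows.

    Constant columns (max == min) are mapped to 0 everywhere with a warning.
    Transformed values are NOT clipped: rows outside the training range map
    outside [0, 1], documenting extrapolation honestly.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.n_features_in_ = X.shape[1]
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        rng = self.data_max_ - self.data_min_
        degenerate = rng == 0
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} constant column(s) mapped to 0 under "
                "min-max scaling",
                UserWarning,
                stacklevel=2,
            )
        self.scale_ = np.where(degenerate, np.inf, rng)
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, scaler was fitted on "
                f"{self.n_features_in_}"
            )
        return (X - self.data_min_) / self.scale_

    def to_dict(self) -> dict:
        check_is_fitted(self, "data_min_")
        return {
            "col_min": self.data_min_.tolist(),
            "col_max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        obj = cls()
        obj.data_min_ = np.asarray(d["col_min"], dtype=float)
        obj.data_max_ = np.asarray(d["col_max"], dtype=float)
        rng = obj.data_max_ - obj.data_min_
        obj.scale_ = np.where(rng == 0, np.inf, rng)
        obj.n_features_in_ = len(obj.data_min_)
        return obj


class PCA(BaseEstimator, TransformerMixin):
    """Principal component analysis by covariance eigendecomposition.

    Components are the top ``n_components`` eigenvectors of the sample
    covariance (divisor n-1), sorted by explained variance descending.  Each
    axis's sign is fixed so its largest-magnitude loading is positive, making
    repeated fits reproducible.
    """

    def __init__(self, n_components: int = 8):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        k = int(self.n_components)
        if not 1 <= k <= X.shape[1]:
            raise ValueError(
                f"n_components={k} must lie in [1, {X.shape[1]}] for this data"
            )
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        cov = np.cov(X - self.mean_, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:k]
        components = evecs[:, order].T
        # sign convention: largest-|loading| entry of each axis is positive
        flip = np.sign(
            components[np.arange(k), np.abs(components).argmax(axis=1)]
        )
        flip[flip == 0] = 1.0
        self.components_ = components * flip[:, None]
        self.explained_variance_ = np.maximum(evals[order], 0.0)
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, PCA was fitted on "
                f"{self.n_features_in_}"
            )
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, Z):
        check_is_fitted(self, "components_")
        return np.asarray(Z) @ self.components_ + self.mean_

    def to_dict(self) -> dict:
        check_is_fitted(self, "components_")
        return {
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "k": int(self.components_.shape[0]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCA":
        obj = cls(n_components=int(d["k"]))
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.components_ = np.asarray(d["components"], dtype=float)
        obj.n_features_in_ = obj.components_.shape[1]
        obj.explained_variance_ = np.asarray(d.get("explained_variance", []), dtype=float)
        return obj


# ---------------------------------------------------------------------------
# Functional wrappers matching the operation-level interface.

def fit_minmax(train: FeatureTable) -> MinMaxScaler:
    return MinMaxScaler().fit(train.values)


def apply_minmax(table: FeatureTable, params: MinMaxScaler) -> FeatureTable:
    return table.with_values(params.transform(table.values))


def fit_pca(train: FeatureTable, k: int) -> PCA:
    return PCA(n_components=k).fit(train.values)


def apply_pca(table: FeatureTable, params: PCA) -> FeatureTable:
    z = params.transform(table.values)
    names = [f"pc{i + 1}" for i in range(z.shape[1])]
    return table.with_values(z, column_names=names)


def save_params(path, scaler: MinMaxScaler | None = None, pca: PCA | None = None) -> None:
    """Serialize fitted scaling/PCA parameters to a flat JSON file."""
    payload: dict = {}
    if scaler is not None:
        payload["minmax"] = scaler.to_dict()
    if pca is not None:
        payload["pca"] = pca.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_params(path) -> tuple[MinMaxScaler | None, PCA | None]:
    with open(path) as fh:
        payload = json.load(fh)
    scaler = MinMaxScaler.from_dict(payload["minmax"]) if "minmax" in payload else None
    pca = PCA.from_dict(payload["pca"]) if "pca" in payload else None
    return scaler, pca


# ---------------------------------------------------------------------------
# CSV input contract: header row, 13 predictor columns + 1 label column.

_LABEL_TOKENS = {
    "0": 0, "absence": 0, "absent": 0, "no": 0,
    "1": 1, "presence": 1, "present": 1, "yes": 1,
}


def _coerce_labels(col: pd.Series) -> np.ndarray:
    tokens = col.astype(str).str.strip().str.lower()
    unknown = sorted(set(tokens) - set(_LABEL_TOKENS))
    if unknown:
        raise ValueError(
            f"label column contains unrecognized values {unknown}; expected "
            "0/1 or absence/presence"
        )
    return tokens.map(_LABEL_TOKENS).to_numpy(dtype=int)


def read_table(path, label_col: str = "class") -> FeatureTable:
    """Read a CSV with a header row into a FeatureTable.

    The label column (default ``class``) accepts 0/1 or absence/presence
    tokens.  Non-numeric feature columns are label-encoded lexicographically.
    """
    df = pd.read_csv(path)
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {list(df.columns)}")
    labels = _coerce_labels(df[label_col])
    feats = df.drop(columns=[label_col])
    if feats.shape[1] < 1:
        raise ValueError("no feature columns found")
    values = np.empty(feats.shape, dtype=float)
    for j, name in enumerate(feats.columns):
        col = feats[name]
        if pd.api.types.is_numeric_dtype(col):
            values[:, j] = col.to_numpy(dtype=float)
        else:
            values[:, j], _ = encode_labels(col.tolist())
    if np.isnan(values).any():
        raise ValueError("feature columns contain missing values")
    return FeatureTable(values, list(feats.columns), labels)


def write_table(table: FeatureTable, path, label_col: str = "class") -> None:
    df = pd.DataFrame(table.values, columns=table.column_names)
    df[label_col] = table.labels
    df.to_csv(path, index=False)
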