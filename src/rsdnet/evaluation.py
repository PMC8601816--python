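"""Splitting protocols, confusion-matrix metrics, lambda sweeps and the
regularizer-by-PCA comparison grid.

The evaluation protocol mirrors the training study: stratified 80/20 holdout
or stratified 10-fold cross-validation; min-max scaling and (optionally) PCA
are fitted inside each split on the training rows only, so no information
leaks from held-out rows (``fit_on_all=True`` reproduces the leakier
fit-once-on-everything variant).  The positive class for sensitivity,
specificity and F-score is "disease present" (label 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import RSDNetClassifier, TrainConfig
from .preprocess import (FeatureTable, apply_minmax, apply_pca, fit_minmax,
                         fit_pca)
from .regularizers import FAMILIES, Regularizer


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_score": self.f_score,
        }


def _check_binary(v, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return v.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with label 1 (disease present) as the positive class."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity (TPR), specificity (TNR) and F-score.

    Any 0/0 ratio is reported as 0 by convention.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero instances")

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    sens = ratio(c.tp, c.tp + c.fn)
    prec = ratio(c.tp, c.tp + c.fp)
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=sens,
        specificity=ratio(c.tn, c.tn + c.fp),
        f_score=ratio(2 * prec * sens, prec + sens),
    )


def _strata(labels: np.ndarray) -> list:
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == c) for c in np.unique(labels)]


def holdout_split(n: int, fraction: float = 0.8, seed: int = 0, labels=None):
    """Stratified train/test index split; reproducible by seed.

    Train size per stratum is round(fraction * stratum size), clamped so both
    sides keep at least one member.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for idx in _strata(labels):
        if len(idx) < 2:
            raise ValueError("every class needs at least 2 members to split")
        perm = rng.permutation(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def kfold_split(n: int, k: int = 10, seed: int = 0, labels=None):
    """Stratified k-fold; test sets are disjoint, cover all indices, and per
    stratum their sizes differ by at most one."""
    if k > n:
        raise ValueError(f"k={k} exceeds the number of instances n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    rng = np.random.default_rng(seed)
    fold_test = [[] for _ in range(k)]
    for idx in _strata(labels):
        perm = rng.permutation(idx)
        for i, j in enumerate(perm):
            fold_test[i % k].append(j)
    splits = []
    all_idx = np.arange(n)
    for te in fold_test:
        te = np.sort(np.array(te, dtype=int))
        tr = np.setdiff1d(all_idx, te)
        splits.append((tr, te))
    return splits


# ---------------------------------------------------------------------------
# Single-run pipeline: preprocess inside the split, train, evaluate.

def _preprocess_split(table: FeatureTable, train_idx, test_idx,
                      use_pca: bool, pca_k: int, fit_on_all: bool):
    fit_tab = table if fit_on_all else table.subset(train_idx)
    scaler = fit_minmax(fit_tab)
    scaled = apply_minmax(table, scaler)
    if use_pca:
        pca = fit_pca(scaled if fit_on_all else scaled.subset(train_idx), pca_k)
        scaled = apply_pca(scaled, pca)
    return scaled.subset(train_idx), scaled.subset(test_idx)


def _make_clf(reg: Regularizer, seed: int, train_cfg: TrainConfig) -> RSDNetClassifier:
    return RSDNetClassifier(
        hidden_layer_sizes=train_cfg.hidden_layer_sizes,
        family=reg.family, lam=reg.lam, alpha=reg.alpha, rsd_mode=reg.rsd_mode,
        epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
        learning_rate=train_cfg.learning_rate, beta1=train_cfg.beta1,
        beta2=train_cfg.beta2, eps=train_cfg.eps_opt,
        init_std=train_cfg.init_std, random_state=seed,
    )


def run_split(table: FeatureTable, train_idx, test_idx, reg: Regularizer,
              seed: int, use_pca: bool = False, pca_k: int = 8,
              fit_on_all: bool = False,
              train_cfg: TrainConfig | None = None):
    """Preprocess within one split, train, and return (MetricsReport, history)."""
    cfg = train_cfg or TrainConfig()
    tr, te = _preprocess_split(table, train_idx, test_idx, use_pca, pca_k, fit_on_all)
    clf = _make_clf(reg, seed, cfg)
    clf.fit(tr.values, tr.labels, validation_data=(te.values, te.labels))
    pred = clf.predict(te.values)
    return compute_metrics(confusion(te.labels, pred)), clf.history_


def evaluate_config(table: FeatureTable, reg: Regularizer, seed: int,
                    use_pca: bool = False, pca_k: int = 8,
                    split: str = "holdout", fraction: float = 0.8,
                    folds: int = 10, fit_on_all: bool = False,
                    train_cfg: TrainConfig | None = None):
    """One full evaluation at a fixed seed.

    Returns (mean validation accuracy, list of per-fold MetricsReport); the
    holdout protocol yields a single-entry list.
    """
    n = table.n_rows
    if split == "holdout":
        pairs = [holdout_split(n, fraction, seed=seed, labels=table.labels)]
    elif split == "kfold":
        pairs = kfold_split(n, folds, seed=seed, labels=table.labels)
    else:
        raise ValueError(f"unknown split mode {split!r}")
    reports = []
    for tr_idx, te_idx in pairs:
        rep, _ = run_split(table, tr_idx, te_idx, reg, seed, use_pca, pca_k,
                           fit_on_all, train_cfg)
        reports.append(rep)
    return float(np.mean([r.accuracy for r in reports])), reports


def lambda_sweep(table: FeatureTable, family: str, lambda_grid,
                 use_pca: bool = False, pca_k: int = 8, repeats: int = 10,
                 base_seed: int = 0, alpha: float = 0.5,
                 split: str = "holdout", folds: int = 10,
                 fit_on_all: bool = False,
                 train_cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Validation accuracy across a lambda grid.

    Each lambda is evaluated ``repeats`` times with seeds base_seed..base_seed+
    repeats-1 (fresh split, init and shuffle order per seed); rows report the
    mean and sd across repeats plus the raw per-repeat accuracies.
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda grid must be nonempty")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    rows = []
    for lam in lambda_grid:
        reg = Regularizer(family=family, lam=lam, alpha=alpha)
        accs, fold_accs = [], []
        for i in range(repeats):
            acc, reports = evaluate_config(
                table, reg, seed=base_seed + i, use_pca=use_pca, pca_k=pca_k,
                split=split, folds=folds, fit_on_all=fit_on_all,
                train_cfg=train_cfg)
            accs.append(acc)
            fold_accs.append([r.accuracy for r in reports])
        rows.append({
            "family": family,
            "use_pca": use_pca,
            "lambda": lam,
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)) if repeats > 1 else 0.0,
            "accuracies": accs,
            "fold_accuracies": fold_accs,
        })
    return pd.DataFrame(rows)


def compare_regularizers(table: FeatureTable, families=FAMILIES,
                         lambda_grids=None, pca_k: int = 8, repeats: int = 10,
                         base_seed: int = 0, alpha: float = 0.5,
                         split: str = "holdout", folds: int = 10,
                         fit_on_all: bool = False,
                         train_cfg: TrainConfig | None = None):
    """Full family-by-PCA grid; returns (summary, full grid) DataFrames.

    For each family and PCA mode the best lambda from a sweep is reported
    with its mean validation accuracy, shaped like the study's comparison
    table (one row per family, with/without-PCA accuracy columns in %).
    """
    if lambda_grids is None:
        lambda_grids = {}
    default_grid = [1e-8, 1e-6]
    grids = {f: list(lambda_grids.get(f, lambda_grids.get("default", default_grid)))
             if isinstance(lambda_grids, dict) else list(lambda_grids)
             for f in families}
    summary_rows, grid_frames = [], []
    for family in families:
        row = {"family": family}
        for use_pca in (False, True):
            sweep = lambda_sweep(
                table, family, grids[family], use_pca=use_pca, pca_k=pca_k,
                repeats=repeats, base_seed=base_seed, alpha=alpha, split=split,
                folds=folds, fit_on_all=fit_on_all, train_cfg=train_cfg)
            grid_frames.append(sweep)
            best = sweep.loc[sweep["mean_accuracy"].idxmax()]
            key = "with_pca" if use_pca else "without_pca"
            row[f"{key}_accuracy_pct"] = 100.0 * best["mean_accuracy"]
            row[f"{key}_best_lambda"] = best["lambda"]
        summary_rows.append(row)
    return pd.DataFrame(summary_rows), pd.concat(grid_frames, ignore_index=True)
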