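"""Hyperparameter-optimized decision-tree classification of ROI features.

Reproduces the study's training protocol on a milestone feature table:
an "optimisable tree" selected by grid search over decision-tree
hyperparameters under 10-fold cross-validation, with an 80:20 stratified
train:test split, reported as a confusion matrix with overall accuracy,
lesion-positive PPV and per-class TPR/FNR.

Cross-validation folds are assigned by hashing roi_id together with the
seed, so fold membership is reproducible and independent of row order.
Missing features are imputed strictly within the training side of each
fold (and within the training split for the final model): the post-peak
outflow features (delta10, slope10/20/60) impute to 0 — a peak at or
beyond the window end means no washout was observable, so the measured
outflow is zero, and a cohort median (dominated by washing-out lesions)
would be misleading — while all other features impute to the training
median.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidParameterError
from .reference import FEATURE_ORDER

__all__ = [
    "FittedClassifier",
    "ClassifierReport",
    "split",
    "assign_folds",
    "optimize_tree",
    "evaluate",
]

FEATURE_COLUMNS: tuple[str, ...] = FEATURE_ORDER
LABEL_ORDER: tuple[str, ...] = ("crlm", "healthy", "benign_cyst")

TREE_GRID = {
    "max_depth": list(range(1, 11)),
    "min_samples_leaf": [1, 2, 5, 10, 20],
    "criterion": ["gini", "entropy"],
}
# CART breaks exact impurity ties through a random feature permutation; the
# search tries several tie-break states per configuration and scores them by
# the same CV accuracy, so fragile narrow-margin splits lose the selection
N_TIEBREAK_STATES = 3

# outflow features whose absence means "no washout observed in the window";
# imputed as 0 rather than the cohort median
ZERO_IMPUTED = ("delta10", "slope10", "slope20", "slope60")


def _fill_values(X: pd.DataFrame) -> pd.Series:
    fill = X.median()
    for col in X.columns:
        if col in ZERO_IMPUTED:
            fill[col] = 0.0
    return fill.fillna(0.0)


def _ordered_labels(present: set[str]) -> list[str]:
    known = [l for l in LABEL_ORDER if l in present]
    return known + sorted(present - set(LABEL_ORDER))


def split(
    table: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    group_by_patient: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split, deterministic per seed.

    ``group_by_patient`` keeps each patient's ROIs on one side (off by
    default, mirroring an ROI-level split).
    """
    if not 0 < test_fraction < 1:
        raise InvalidParameterError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list = []
    for label, group in table.groupby("label", sort=True):
        if len(group) < 2:
            raise InvalidParameterError(
                f"label {label!r} has {len(group)} row(s); need >= 2 to stratify"
            )
        if group_by_patient:
            pids = sorted(group["patient_id"].unique())
            rng.shuffle(pids)
            n_test = max(1, int(round(test_fraction * len(pids))))
            chosen = set(pids[:n_test])
            test_idx.extend(group.index[group["patient_id"].isin(chosen)])
        else:
            order = np.array(group.index)
            rng.shuffle(order)
            n_test = min(max(1, int(round(test_fraction * len(group)))), len(group) - 1)
            test_idx.extend(order[:n_test])
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()


def assign_folds(roi_ids: pd.Index | list[str], seed: int, folds: int) -> np.ndarray:
    """Deterministic, row-order independent fold id per roi_id."""
    out = np.empty(len(roi_ids), dtype=int)
    for i, rid in enumerate(roi_ids):
        digest = hashlib.md5(f"{rid}|{seed}".encode()).hexdigest()
        out[i] = int(digest, 16) % folds
    return out


@dataclass
class FittedClassifier:
    """A trained tree plus everything needed to reproduce its selection."""

    estimator: DecisionTreeClassifier
    feature_columns: tuple[str, ...]
    medians: pd.Series  # training-split imputation values (0 for outflow)
    best_params: dict
    cv_accuracy: float  # mean out-of-fold accuracy, in [0, 1]
    per_class_cv_accuracy: dict[str, float]
    oof_predictions: pd.Series  # indexed by roi_id
    cv_results: pd.DataFrame = field(repr=False, default=None)
    family: str = "decision_tree"

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.feature_columns)].fillna(self.medians)
        return self.estimator.predict(X.to_numpy())

    def tree_as_dict(self) -> dict:
        """JSON-serializable tree structure (feature, threshold, children)."""
        t = self.estimator.tree_
        classes = list(self.estimator.classes_)

        def node(i: int) -> dict:
            if t.children_left[i] == -1:
                counts = t.value[i][0]
                return {"leaf": classes[int(np.argmax(counts))],
                        "counts": dict(zip(classes, counts.tolist()))}
            return {
                "feature": self.feature_columns[t.feature[i]],
                "threshold": float(t.threshold[i]),
                "left": node(t.children_left[i]),
                "right": node(t.children_right[i]),
            }

        return {"family": self.family, "params": self.best_params, "tree": node(0)}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model": self.tree_as_dict(),
                    "feature_columns": list(self.feature_columns),
                    "medians": {k: float(v) for k, v in self.medians.items()},
                    "cv_accuracy": self.cv_accuracy,
                },
                fh,
                indent=2,
            )


def _xy(table: pd.DataFrame, feature_columns) -> tuple[pd.DataFrame, np.ndarray]:
    missing = [c for c in feature_columns if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"feature table lacks columns {missing}")
    return table[list(feature_columns)], table["label"].to_numpy()


def optimize_tree(
    train: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
) -> FittedClassifier:
    """Grid-search a decision tree under k-fold CV and refit on all rows.

    Selection maximizes mean out-of-fold accuracy; ties prefer the smaller
    depth, then the larger minimum leaf size (simpler trees). The final
    model is refit on the full training table with its own medians.
    """
    X, y = _xy(train, feature_columns)
    labels = set(y)
    if len(labels) < 2:
        raise InvalidParameterError("training table has a single class")
    if folds > len(train):
        warnings.warn(
            f"folds={folds} exceeds {len(train)} rows; reducing to {len(train)}",
            stacklevel=2,
        )
        folds = len(train)
    scarce = {l for l in labels if (y == l).sum() < folds}
    if scarce:
        warnings.warn(
            f"classes {sorted(scarce)} have fewer rows than folds={folds}; "
            "some folds will lack them in the held-out part",
            stacklevel=2,
        )

    fold_ids = assign_folds(train["roi_id"], seed, folds)
    fold_cache = []
    for f in range(folds):
        hold = fold_ids == f
        if not hold.any():
            continue
        med = _fill_values(X[~hold])
        fold_cache.append(
            (
                X[~hold].fillna(med).to_numpy(),
                y[~hold],
                X[hold].fillna(med).to_numpy(),
                y[hold],
                hold,
            )
        )

    results = []
    best = None
    n = len(train)
    for depth in TREE_GRID["max_depth"]:
        for leaf in TREE_GRID["min_samples_leaf"]:
            for crit in TREE_GRID["criterion"]:
                for state_i in range(N_TIEBREAK_STATES):
                    state = (seed + 1_000_003 * state_i) % (2**32)
                    est = DecisionTreeClassifier(
                        max_depth=depth,
                        min_samples_leaf=leaf,
                        criterion=crit,
                        random_state=state,
                    )
                    oof = np.empty(n, dtype=object)
                    for Xtr, ytr, Xho, yho, hold in fold_cache:
                        m = clone(est).fit(Xtr, ytr)
                        oof[hold] = m.predict(Xho)
                    acc = float(np.mean(oof == y))
                    results.append(
                        {"max_depth": depth, "min_samples_leaf": leaf,
                         "criterion": crit, "tiebreak_state": state_i,
                         "cv_accuracy": acc}
                    )
                    key = (acc, -depth, leaf, -state_i)
                    if best is None or key > best[0]:
                        best = (key, est, {"max_depth": depth,
                                           "min_samples_leaf": leaf,
                                           "criterion": crit,
                                           "tiebreak_state": state_i}, oof)

    _, best_est, best_params, best_oof = best
    medians = _fill_values(X)
    final = clone(best_est).fit(X.fillna(medians).to_numpy(), y)
    per_class = {
        l: float(np.mean(best_oof[y == l] == l)) for l in _ordered_labels(labels)
    }
    return FittedClassifier(
        estimator=final,
        feature_columns=tuple(feature_columns),
        medians=medians,
        best_params=best_params,
        cv_accuracy=float(np.mean(best_oof == y)),
        per_class_cv_accuracy=per_class,
        oof_predictions=pd.Series(best_oof, index=train["roi_id"], name="oof_prediction"),
        cv_results=pd.DataFrame(results),
    )


@dataclass
class ClassifierReport:
    """Confusion matrix and headline percentages for a test split.

    Percentages are reported to one decimal. ``positive_label`` (lesion)
    defines the PPV: TP / (TP + FP) against all other classes.
    """

    labels: list[str]
    matrix: np.ndarray  # (true x predicted) counts
    accuracy_pct: float
    ppv_pct: float
    tpr_pct: dict[str, float]
    fnr_pct: dict[str, float]
    positive_label: str = "crlm"
    unseen_labels: list[str] = field(default_factory=list)

    def summary(self) -> str:
        width = max(len(l) for l in self.labels) + 2
        head = " " * width + "".join(f"{l:>{width}}" for l in self.labels)
        rows = [head]
        for i, l in enumerate(self.labels):
            rows.append(
                f"{l:>{width}}" + "".join(f"{int(c):>{width}}" for c in self.matrix[i])
            )
        rows.append(f"accuracy {self.accuracy_pct:.1f} %  "
                    f"PPV({self.positive_label}) {self.ppv_pct:.1f} %")
        for l in self.labels:
            rows.append(f"  {l}: TPR {self.tpr_pct[l]:.1f} %  FNR {self.fnr_pct[l]:.1f} %")
        return "\n".join(rows)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "matrix": self.matrix.tolist(),
            "accuracy_pct": self.accuracy_pct,
            "ppv_pct": self.ppv_pct,
            "tpr_pct": self.tpr_pct,
            "fnr_pct": self.fnr_pct,
            "positive_label": self.positive_label,
        }


def report_from_predictions(
    y_true, y_pred, positive_label: str = "crlm", known_labels=None
) -> ClassifierReport:
    """Build the report from true/predicted label arrays."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    present = set(y_true) | set(y_pred)
    unseen = sorted(present - set(known_labels)) if known_labels is not None else []
    labels = _ordered_labels(present)
    index = {l: i for i, l in enumerate(labels)}
    matrix = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        matrix[index[t], index[p]] += 1
    total = matrix.sum()
    accuracy = 100.0 * np.trace(matrix) / total
    if positive_label in index:
        i = index[positive_label]
        tp = matrix[i, i]
        fp = matrix[:, i].sum() - tp
        ppv = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
    else:
        ppv = float("nan")
    tpr, fnr = {}, {}
    for l, i in index.items():
        row = matrix[i].sum()
        tpr[l] = round(100.0 * matrix[i, i] / row, 1) if row else float("nan")
        fnr[l] = round(100.0 - tpr[l], 1) if row else float("nan")
    return ClassifierReport(
        labels=labels,
        matrix=matrix,
        accuracy_pct=round(accuracy, 1),
        ppv_pct=round(ppv, 1) if np.isfinite(ppv) else ppv,
        tpr_pct=tpr,
        fnr_pct=fnr,
        positive_label=positive_label,
        unseen_labels=unseen,
    )


def evaluate(
    clf: FittedClassifier, test: pd.DataFrame, positive_label: str = "crlm"
) -> ClassifierReport:
    """Confusion matrix, accuracy, PPV and per-class TPR/FNR on a test split."""
    if len(test) == 0:
        raise InvalidParameterError("test table is empty")
    y_pred = clf.predict(test)
    y_true = test["label"].to_numpy()
    report = report_from_predictions(
        y_true, y_pred, positive_label, known_labels=set(clf.estimator.classes_)
    )
    if report.unseen_labels:
        warnings.warn(
            f"test labels {report.unseen_labels} unseen during training; "
            "counted as error classes",
            stacklevel=2,
        )
    return report
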