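"""Classifiers, participant-level cross-validation, and the metrics panel.

Two primary models: a quadratic-kernel SVM (K(x, z) = (1 + x.z)^2, box
constraint 1) and a narrow feedforward network (one hidden layer of 10
ReLU units trained by mini-batch SGD with momentum). Fold assignment is
stratified by class at the participant level so no participant's segments
straddle a train/test boundary.

Label convention: asthma = 1 (positive class), healthy = 2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix, relieff, select_top_k, standardize

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "QSVMConfig",
    "NNNConfig",
    "KNNConfig",
    "CVPlan",
    "EvalReport",
    "participant_folds",
    "train_quadratic_svm",
    "train_narrow_nn",
    "train_knn",
    "make_model",
    "positive_scores",
    "run_cv",
    "classification_metrics",
    "f1_from_precision_recall",
    "roc_pr_curves",
]

POSITIVE_LABEL = 1  # asthma
NEGATIVE_LABEL = 2  # healthy


@dataclass(frozen=True)
class QSVMConfig:
    """Quadratic-kernel SVM: (1 + x.z)^2 with unit kernel scale."""

    box_constraint: float = 1.0
    order: int = 2

    def __post_init__(self) -> None:
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")
        if self.order != 2:
            raise ValueError("kernel order is fixed at 2")


@dataclass(frozen=True)
class NNNConfig:
    """Narrow feedforward network trained with SGD + momentum."""

    hidden_units: int = 10
    learning_rate: float = 0.01
    max_epochs: int = 30
    batch_size: int = 128
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_units, self.max_epochs, self.batch_size) <= 0:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class KNNConfig:
    """Fine kNN preset used for external-validation style runs."""

    n_neighbors: int = 1
    metric: str = "euclidean"


def train_quadratic_svm(X: np.ndarray, y: np.ndarray, config: QSVMConfig | None = None) -> SVC:
    """Fit the soft-margin dual with kernel (1 + x.z)^2; exposes decision values."""
    config = config or QSVMConfig()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = SVC(
        kernel="poly",
        degree=config.order,
        gamma=1.0,
        coef0=1.0,
        C=config.box_constraint,
    )
    model.fit(X, y)
    return model


def train_narrow_nn(
    X: np.ndarray, y: np.ndarray, config: NNNConfig | None = None
) -> MLPClassifier:
    """Fit a 1x10 ReLU network; training is seed-deterministic."""
    config = config or NNNConfig()
    model = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="relu",
        solver="sgd",
        learning_rate_init=config.learning_rate,
        momentum=config.momentum,
        nesterovs_momentum=False,
        max_iter=config.max_epochs,
        batch_size=min(config.batch_size, len(X)),
        alpha=0.0,
        tol=0.0,
        n_iter_no_change=config.max_epochs,
        shuffle=True,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    if not np.all(np.isfinite(model.loss_curve_)):
        bad = int(np.flatnonzero(~np.isfinite(model.loss_curve_))[0]) + 1
        raise RuntimeError(f"NaN loss at epoch {bad}")
    return model


def train_knn(X: np.ndarray, y: np.ndarray, config: KNNConfig | None = None):
    config = config or KNNConfig()
    model = KNeighborsClassifier(n_neighbors=config.n_neighbors, metric=config.metric)
    model.fit(X, y)
    return model


MODEL_BUILDERS = {
    "qsvm": train_quadratic_svm,
    "nnn": train_narrow_nn,
    "knn": train_knn,
    # wide NN: identical trainer, 100 hidden units (config preset)
    "wide_nn": lambda X, y, config=None: train_narrow_nn(
        X, y, config or NNNConfig(hidden_units=100)
    ),
}


def make_model(name: str, X: np.ndarray, y: np.ndarray, config=None):
    try:
        builder = MODEL_BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_BUILDERS)}")
    return builder(X, y, config)


def positive_scores(model, X: np.ndarray, positive_label: int = POSITIVE_LABEL) -> np.ndarray:
    """Continuous scores increasing with confidence in the positive class."""
    classes = list(model.classes_)
    if hasattr(model, "decision_function"):
        scores = model.decision_function(X)
        # sklearn's decision favours classes_[1]; flip if positive is classes_[0]
        return scores if classes[1] == positive_label else -scores
    proba = model.predict_proba(X)
    return proba[:, classes.index(positive_label)]


@dataclass
class CVPlan:
    """Participant -> fold assignment, stratified by class."""

    assignment: dict[str, int]
    n_folds: int
    seed: int

    def fold_of(self, participant_ids: np.ndarray) -> np.ndarray:
        return np.array([self.assignment[p] for p in participant_ids])

    def fold_indices(
        self, participant_ids: np.ndarray
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-fold (train_rows, test_rows) over segment rows."""
        folds = self.fold_of(np.asarray(participant_ids))
        out = []
        for f in range(self.n_folds):
            test = np.flatnonzero(folds == f)
            train = np.flatnonzero(folds != f)
            out.append((train, test))
        return out


def participant_folds(
    participants: pd.DataFrame | dict[str, int], n_folds: int = 10, seed: int = 0
) -> CVPlan:
    """Stratified fold plan at the participant level.

    ``participants`` maps participant_id -> class label (or is a DataFrame
    with those columns). Participants are shuffled within class with the
    given seed, then dealt round-robin so every fold holds 1/n_folds of
    each class (plus/minus one).
    """
    if isinstance(participants, pd.DataFrame):
        pairs = (
            participants[["participant_id", "label"]]
            .drop_duplicates("participant_id")
            .itertuples(index=False)
        )
        mapping = {p: int(l) for p, l in pairs}
    else:
        mapping = dict(participants)
    labels = np.array(sorted(set(mapping.values())))
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for label in labels:
        pids = sorted(p for p, l in mapping.items() if l == label)
        if len(pids) < n_folds:
            raise ValueError(
                f"class {label} has {len(pids)} participants, fewer than "
                f"n_folds={n_folds}"
            )
        rng.shuffle(pids)
        for i, pid in enumerate(pids):
            assignment[pid] = i % n_folds
    return CVPlan(assignment=assignment, n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean, on whatever scale the inputs share (e.g. percent)."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Panel of percent metrics from confusion counts (positive = asthma).

    Zero-denominator metrics are reported as NaN.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn

    def _ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    return {
        "accuracy": _ratio(tp + tn, total),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": _ratio(tn, tn + fp),
        "f1": f1_from_precision_recall(precision, sensitivity),
    }


def roc_pr_curves(
    scores: np.ndarray, labels: np.ndarray, positive_label: int = POSITIVE_LABEL
) -> dict:
    """ROC and PR curves with AUCs from a threshold sweep over unique scores.

    ROC-AUC by trapezoid; PR-AUC by interpolation-free step summation
    (sum of precision * recall increments).
    """
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(labels) == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC/PR curves")
    order = np.argsort(-scores, kind="stable")
    pos_sorted = pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # collapse tied scores: keep the last index of each distinct value
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(scores) - 1]
    tps, fps = tps[distinct], fps[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    roc_auc = float(np.trapezoid(tpr, fpr))
    precision = tps / (tps + fps)
    recall = tps / n_pos
    pr_auc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_auc": roc_auc,
        "precision": np.r_[1.0, precision],
        "recall": np.r_[0.0, recall],
        "pr_auc": pr_auc,
    }


@dataclass
class EvalReport:
    """Fold-aggregated confusion matrix, metric panel and curves."""

    confusion: dict[str, int]  # tp, fp, tn, fn over all test folds
    metrics: dict[str, float]  # percent, aggregate confusion
    per_fold: list[dict]  # fold index + metric panel per fold
    roc: dict | None = None
    model_name: str = ""
    n_folds: int = 0

    def to_dict(self) -> dict:
        out = {
            "model": self.model_name,
            "n_folds": self.n_folds,
            "confusion": self.confusion,
            "metrics": {k: round(v, 2) for k, v in self.metrics.items()},
            "metrics_full_precision": self.metrics,
            "per_fold": self.per_fold,
        }
        if self.roc is not None:
            out["roc_auc"] = self.roc["roc_auc"]
            out["pr_auc"] = self.roc["pr_auc"]
        return out


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    pos_t = y_true == POSITIVE_LABEL
    pos_p = y_pred == POSITIVE_LABEL
    return {
        "tp": int(np.sum(pos_t & pos_p)),
        "fp": int(np.sum(~pos_t & pos_p)),
        "tn": int(np.sum(~pos_t & ~pos_p)),
        "fn": int(np.sum(pos_t & ~pos_p)),
    }


def run_cv(
    matrix: FeatureMatrix,
    plan: CVPlan,
    model_name: str = "qsvm",
    model_config=None,
    select_k: int | None = 10,
    relieff_k_neighbors: int = 10,
    with_curves: bool = True,
) -> EvalReport:
    """Cross-validate with per-fold standardization, selection and training.

    Within each fold, standardization parameters and the ReliefF ranking
    are fitted on training rows only; confusion counts are aggregated over
    the test folds and the metric panel is computed on the aggregate (and
    per fold). ``select_k=None`` disables feature selection.
    """
    X, y = matrix.values, matrix.labels
    folds = plan.fold_indices(matrix.groups)
    agg = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    per_fold = []
    all_scores, all_true = [], []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        if len(test_idx) == 0:
            continue
        Xs_train, tf = standardize(X[train_idx])
        Xs_test = tf.transform(X[test_idx])
        if select_k is not None and select_k < X.shape[1]:
            res = relieff(
                Xs_train, y[train_idx], k_neighbors=relieff_k_neighbors, n_select=select_k
            )
            cols = np.sort(res.ranking[:select_k])
            Xs_train, Xs_test = Xs_train[:, cols], Xs_test[:, cols]
        model = make_model(model_name, Xs_train, y[train_idx], model_config)
        pred = model.predict(Xs_test)
        cm = _confusion(y[test_idx], pred)
        for key in agg:
            agg[key] += cm[key]
        per_fold.append({"fold": fold_id, "n_test": len(test_idx), **classification_metrics(**cm)})
        if with_curves:
            all_scores.append(positive_scores(model, Xs_test))
            all_true.append(y[test_idx])
    roc = None
    if with_curves and all_scores:
        roc = roc_pr_curves(np.concatenate(all_scores), np.concatenate(all_true))
    return EvalReport(
        confusion=agg,
        metrics=classification_metrics(**agg),
        per_fold=per_fold,
        roc=roc,
        model_name=model_name,
        n_folds=plan.n_folds,
    )
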