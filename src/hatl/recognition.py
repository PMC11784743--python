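"""Emotion-recognition ensemble and classification metrics.

Three classifiers — an RBF-kernel SVM (C=1.0, gamma='scale'), a 100-tree
random forest and a single-hidden-layer MLP (100 ReLU units, Adam, lr 1e-3,
200 iterations) — are trained on the fused feature matrix and their metrics
averaged, so no single model biases the comparison between real, generated
and non-EEG-only feature sets. Metrics are computed from one-vs-rest
confusion counts; ROC curves are macro-averaged over classes on a common
false-positive-rate grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .data import ScalerState, minmax_scale

__all__ = [
    "ClassifierConfig",
    "ConfusionCounts",
    "MetricsResult",
    "fuse_and_scale",
    "classification_metrics",
    "train_eval_ensemble",
    "macro_roc_auc",
]

CLASSIFIER_NAMES = ("svm", "rf", "mlp")


@dataclass(frozen=True)
class ClassifierConfig:
    svm_c: float = 1.0
    svm_gamma: str = "scale"
    rf_trees: int = 100
    rf_max_depth: int | None = None
    rf_criterion: str = "gini"
    mlp_hidden: int = 100
    mlp_lr: float = 1e-3
    mlp_max_iter: int = 200


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])


@dataclass
class MetricsResult:
    per_classifier: dict[str, dict[str, float]]
    roc_fpr: np.ndarray | None = None
    roc_tpr: dict[str, np.ndarray] = field(default_factory=dict)
    auc: dict[str, float] = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        return float(np.mean([m[metric] for m in self.per_classifier.values()]))

    @property
    def mean_accuracy(self) -> float:
        return self.mean("accuracy")


def fuse_and_scale(eeg: np.ndarray | None, noneeg: np.ndarray,
                   eeg_state: ScalerState | None = None,
                   noneeg_state: ScalerState | None = None,
                   ) -> tuple[np.ndarray, ScalerState, ScalerState | None]:
    """Column-concatenate EEG and non-EEG features and min-max scale.

    States are fitted when not provided (training data) and reused otherwise
    (test data, clipped to [0, 1] so test rows cannot leave the train scale).
    EEG may be None for the non-EEG-only condition.
    """
    noneeg = np.atleast_2d(noneeg)
    if eeg is not None:
        eeg = np.atleast_2d(eeg)
        if eeg.shape[0] != noneeg.shape[0]:
            raise ValueError("EEG and non-EEG row counts differ")
        Xe, eeg_state = minmax_scale(eeg, eeg_state, clip=eeg_state is not None)
    else:
        Xe, eeg_state = None, None
    Xs, noneeg_state = minmax_scale(noneeg, noneeg_state,
                                    clip=noneeg_state is not None)
    design = Xs if Xe is None else np.hstack([Xe, Xs])
    return design, noneeg_state, eeg_state


def classification_metrics(truth: np.ndarray, predicted: np.ndarray,
                           classes: np.ndarray,
                           ) -> tuple[float, float, float, ConfusionCounts]:
    """(accuracy, macro precision, macro recall, confusion counts).

    Accuracy is the fraction of correct predictions (equivalently the sum of
    one-vs-rest true positives over n); precision and recall are macro
    averages, with empty-denominator classes contributing 0.
    """
    truth, predicted = np.asarray(truth), np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    classes = np.asarray(classes)
    unknown = np.setdiff1d(np.union1d(truth, predicted), classes)
    if unknown.size:
        raise ValueError(f"labels outside the class set: {unknown.tolist()}")
    k, n = classes.size, truth.size
    tp = np.zeros(k, int)
    tn = np.zeros(k, int)
    fp = np.zeros(k, int)
    fn = np.zeros(k, int)
    for i, c in enumerate(classes):
        t, p = truth == c, predicted == c
        tp[i] = int((t & p).sum())
        tn[i] = int((~t & ~p).sum())
        fp[i] = int((~t & p).sum())
        fn[i] = int((t & ~p).sum())
    accuracy = tp.sum() / n
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
    return (float(accuracy), float(prec.mean()), float(rec.mean()),
            ConfusionCounts(tp, tn, fp, fn))


def _build_classifiers(config: ClassifierConfig, seed: int) -> dict:
    return {
        "svm": SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma,
                   random_state=seed),
        "rf": RandomForestClassifier(
            n_estimators=config.rf_trees, max_depth=config.rf_max_depth,
            criterion=config.rf_criterion, random_state=seed),
        "mlp": MLPClassifier(
            hidden_layer_sizes=(config.mlp_hidden,), activation="relu",
            solver="adam", learning_rate_init=config.mlp_lr,
            max_iter=config.mlp_max_iter, random_state=seed),
    }


def _scores(clf, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Per-class scores for ROC: probabilities when available, otherwise
    decision-function values min-max mapped to [0, 1]."""
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)
    d = clf.decision_function(X)
    if d.ndim == 1:  # binary: expand to two columns
        d = np.column_stack([-d, d])
    lo, hi = d.min(axis=0), d.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return (d - lo) / span


def train_eval_ensemble(train_X: np.ndarray, train_y: np.ndarray,
                        test_X: np.ndarray, test_y: np.ndarray,
                        config: ClassifierConfig | None = None,
                        seed: int = 0, with_roc: bool = False) -> MetricsResult:
    """Fit SVM/RF/MLP with a shared seed and evaluate each on the test set."""
    config = config or ClassifierConfig()
    train_y, test_y = np.asarray(train_y), np.asarray(test_y)
    classes = np.unique(train_y)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    result = MetricsResult(per_classifier={})
    fpr_grid = np.linspace(0.0, 1.0, 101)
    for name, clf in _build_classifiers(config, seed).items():
        with warnings.catch_warnings():
            # fixed-iteration MLP configuration: non-convergence is expected
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(train_X, train_y)
        pred = clf.predict(test_X)
        acc, prec, rec, _ = classification_metrics(test_y, pred, classes)
        result.per_classifier[name] = {
            "accuracy": acc, "precision": prec, "recall": rec}
        if with_roc:
            scores = _scores(clf, test_X, classes)
            (grid, tpr), auc = macro_roc_auc(test_y, scores, classes)
            result.roc_fpr = grid
            result.roc_tpr[name] = tpr
            result.auc[name] = auc
    return result


def macro_roc_auc(truth: np.ndarray, scores: np.ndarray,
                  classes: np.ndarray | None = None,
                  ) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Macro-averaged one-vs-rest ROC curve and its AUC.

    Per class, the ROC is traced by thresholding that class's score column;
    TPR is interpolated onto a common 101-point FPR grid and averaged across
    classes; the AUC is the trapezoidal area of the averaged curve.
    """
    truth = np.asarray(truth)
    scores = np.atleast_2d(np.asarray(scores, float))
    if classes is None:
        classes = np.unique(truth)
    classes = np.asarray(classes)
    if scores.shape[1] != classes.size:
        raise ValueError("need one score column per class")
    if scores.shape[0] != truth.size:
        raise ValueError("scores and truth must have the same number of rows")
    grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    for i, c in enumerate(classes):
        pos = truth == c
        if pos.all() or not pos.any():
            continue  # degenerate one-vs-rest split carries no ROC information
        order = np.argsort(-scores[:, i], kind="stable")
        p = pos[order]
        tps = np.concatenate([[0], np.cumsum(p)])
        fps = np.concatenate([[0], np.cumsum(~p)])
        tpr = tps / tps[-1]
        fpr = fps / fps[-1]
        # evaluate the empirical (step-function) ROC on the common grid:
        # for each grid FPR, the highest TPR reachable at that FPR or less
        idx = np.searchsorted(fpr, grid, side="right") - 1
        tprs.append(np.maximum.accumulate(tpr)[idx])
    if not tprs:
        raise ValueError("no valid one-vs-rest splits for ROC")
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, grid))
    return (grid, mean_tpr), auc
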