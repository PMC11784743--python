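"""Leave-one-subject-out experiment orchestration.

For each fold one subject is held out: the adversarial generator is trained
on all remaining subjects, the held-out subject's *calibration* portion
provides the non-EEG rows (and labels) from which EEG is synthesized and on
which the classifier ensemble is trained, and the *testing* portion — real
EEG plus non-EEG — measures recognition accuracy. Five conditions are
compared: non-EEG features alone, the three adversarial variants, and real
EEG. A calibration sweep varies the fraction of the calibration portion used
and the calibration improvement score CIS = (1 - B/A) * 100 quantifies the
saving.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MultimodalDataset
from .gan import VARIANTS, HatlModel, TrainConfig, synthesize_eeg, train_hatl
from .recognition import (ClassifierConfig, MetricsResult, fuse_and_scale,
                          train_eval_ensemble)

__all__ = [
    "CONDITIONS",
    "SplitPlan",
    "ExperimentResult",
    "CalibrationResult",
    "loso_splits",
    "train_fold_gan",
    "run_condition",
    "run_loso",
    "calibration_sweep",
    "compute_cis",
    "accuracy_ratio",
]

CONDITIONS = ("noneeg", "cgan", "cwgan", "cwgan-gp", "real")

# Fraction of the held-out subject's rows used for calibration, by profile:
# three recording sessions with two used for calibration (2/3), an even
# two-part split (1/2), and an 80/20 split.
_CAL_FRACTION = {"seedv": 2 / 3, "deap": 0.5, "graffitivr": 0.8, "mini": 0.8}


@dataclass
class SplitPlan:
    test_subject: object
    train_subjects: tuple
    cal_idx: np.ndarray  # row indices into the full dataset
    test_idx: np.ndarray

    def __post_init__(self):
        if np.intersect1d(self.cal_idx, self.test_idx).size:
            raise ValueError("calibration and testing portions must be disjoint")
        if self.test_subject in self.train_subjects:
            raise ValueError("training subjects must exclude the test subject")


def loso_splits(dataset: MultimodalDataset,
                cal_fraction: float | None = None) -> list[SplitPlan]:
    """One fold per subject; the held-out subject's rows are partitioned
    chronologically into calibration and testing portions.

    When the dataset carries a session vector and the profile is
    session-based (seedv), sessions 1-2 form the calibration portion and
    session 3 the testing portion; otherwise the profile's fraction (or
    ``cal_fraction``) of the subject's rows, in row order, is calibration.
    """
    subjects = dataset.subjects
    if subjects.size < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    frac = cal_fraction or _CAL_FRACTION.get(dataset.schema.name, 0.8)
    folds = []
    for subj in subjects:
        rows = np.flatnonzero(dataset.subject == subj)
        if dataset.session is not None and dataset.schema.name == "seedv":
            sess = dataset.session[rows]
            last = sess.max()
            cal, test = rows[sess < last], rows[sess == last]
        else:
            n_cal = int(round(frac * rows.size))
            cal, test = rows[:n_cal], rows[n_cal:]
        if cal.size == 0:
            raise ValueError(f"subject {subj!r} has no calibration rows")
        folds.append(SplitPlan(
            test_subject=subj,
            train_subjects=tuple(s for s in subjects if s != subj),
            cal_idx=cal, test_idx=test))
    return folds


def train_fold_gan(dataset: MultimodalDataset, fold: SplitPlan, variant: str,
                   config: TrainConfig, log=None) -> HatlModel:
    """Train one GAN variant on the fold's training subjects (scaled there)."""
    train_mask = np.isin(dataset.subject, fold.train_subjects)
    assert not np.any(dataset.subject[train_mask] == fold.test_subject), \
        "leakage: test subject rows in GAN training data"
    train_ds = dataset.rows(train_mask).scale()
    return train_hatl(train_ds, variant, config, log=log)


def _ensemble_on_fold(dataset, fold, cal_idx, test_idx, condition,
                      model, clf_config, seed, with_roc=False) -> MetricsResult:
    y_cal, y_test = dataset.y[cal_idx], dataset.y[test_idx]
    S_cal, S_test = dataset.S_noneeg[cal_idx], dataset.S_noneeg[test_idx]

    if condition == "noneeg":
        train_X, s_state, _ = fuse_and_scale(None, S_cal)
        test_X, _, _ = fuse_and_scale(None, S_test, noneeg_state=s_state)
    elif condition == "real":
        train_X, s_state, e_state = fuse_and_scale(dataset.X_eeg[cal_idx], S_cal)
        test_X, _, _ = fuse_and_scale(dataset.X_eeg[test_idx], S_test,
                                      eeg_state=e_state, noneeg_state=s_state)
    elif condition in VARIANTS:
        if model is None:
            raise ValueError("generated condition requires a trained GAN")
        # The generator consumes non-EEG rows in its own training scale and
        # emits EEG in [0, 1] of its training scale; real test EEG is mapped
        # into that same scale for a like-for-like comparison.
        from .data import minmax_scale
        s_scaled, _ = minmax_scale(S_cal, model.noneeg_scaler, clip=True)
        X_gen = synthesize_eeg(model, s_scaled, y_cal, seed=seed)
        train_X, s_state, _ = fuse_and_scale(None, S_cal)
        train_X = np.hstack([X_gen, train_X])
        test_eeg, _ = minmax_scale(dataset.X_eeg[test_idx], model.eeg_scaler,
                                   clip=True)
        test_noneeg, _, _ = fuse_and_scale(None, S_test, noneeg_state=s_state)
        test_X = np.hstack([test_eeg, test_noneeg])
    else:
        raise ValueError(f"unknown condition {condition!r}")

    return train_eval_ensemble(train_X, y_cal, test_X, y_test,
                               clf_config, seed=seed, with_roc=with_roc)


def run_condition(dataset: MultimodalDataset, fold: SplitPlan, condition: str,
                  gan_config: TrainConfig | None = None,
                  clf_config: ClassifierConfig | None = None,
                  seed: int = 0, model: HatlModel | None = None,
                  with_roc: bool = False) -> tuple[MetricsResult, HatlModel | None]:
    """Evaluate one condition on one fold.

    ``real``: classifiers train on the held-out subject's real calibration
    EEG fused with non-EEG. GAN conditions: the variant is trained on the
    training subjects (unless ``model`` is supplied), EEG is synthesized from
    the calibration non-EEG rows and labels, and classifiers train on the
    synthetic fusion. ``noneeg``: EEG is never touched. All conditions test
    on the held-out subject's real testing rows.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if condition in VARIANTS and model is None:
        model = train_fold_gan(dataset, fold, condition,
                               gan_config or TrainConfig(seed=seed))
    metrics = _ensemble_on_fold(dataset, fold, fold.cal_idx, fold.test_idx,
                                condition, model, clf_config, seed,
                                with_roc=with_roc)
    return metrics, model


@dataclass
class ExperimentResult:
    conditions: tuple[str, ...]
    per_subject: dict[str, dict]  # condition -> {subject: MetricsResult}

    def grand_mean(self, condition: str, metric: str = "accuracy") -> float:
        vals = [m.mean(metric) for m in self.per_subject[condition].values()]
        return float(np.mean(vals))

    def grand_std(self, condition: str, metric: str = "accuracy") -> float:
        vals = [m.mean(metric) for m in self.per_subject[condition].values()]
        return float(np.std(vals))

    def ratio_vs(self, condition: str, reference: str = "real") -> tuple[float, int]:
        return accuracy_ratio(self.grand_mean(condition),
                              self.grand_mean(reference))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, per_subj in self.per_subject.items():
            for subj, m in per_subj.items():
                for clf, vals in m.per_classifier.items():
                    rows.append({"condition": cond, "subject": subj,
                                 "classifier": clf, **vals})
        return pd.DataFrame(rows)


def run_loso(dataset: MultimodalDataset, conditions=("noneeg", "cwgan-gp", "real"),
             gan_config: TrainConfig | None = None,
             clf_config: ClassifierConfig | None = None,
             seed: int = 0, log=None) -> ExperimentResult:
    """Full LOSO sweep over conditions; fold seed = global seed + fold index."""
    folds = loso_splits(dataset)
    per_subject: dict[str, dict] = {c: {} for c in conditions}
    for i, fold in enumerate(folds):
        fold_seed = seed + i
        models: dict[str, HatlModel] = {}
        for cond in conditions:
            model = None
            if cond in VARIANTS:
                cfg = gan_config or TrainConfig()
                cfg = TrainConfig(**{**cfg.__dict__, "seed": fold_seed})
                model = models.get(cond) or train_fold_gan(dataset, fold, cond, cfg)
                models[cond] = model
            metrics, _ = run_condition(dataset, fold, cond,
                                       clf_config=clf_config,
                                       seed=fold_seed, model=model)
            per_subject[cond][fold.test_subject] = metrics
            if log is not None:
                log(f"fold {i + 1}/{len(folds)} subject={fold.test_subject} "
                    f"condition={cond} accuracy={metrics.mean_accuracy:.3f}")
    return ExperimentResult(conditions=tuple(conditions), per_subject=per_subject)


@dataclass
class CalibrationResult:
    """Accuracy-vs-fraction curves plus the calibration improvement score."""

    curves: dict[str, dict[float, float]]  # condition -> {fraction: mean accuracy}
    baseline_duration: float | None = None  # A
    improved_duration: float | None = None  # B

    @property
    def cis(self) -> float | None:
        if self.baseline_duration is None or self.improved_duration is None:
            return None
        return compute_cis(self.baseline_duration, self.improved_duration)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"condition": c, "fraction": f, "accuracy": a}
                for c, curve in self.curves.items() for f, a in curve.items()]
        return pd.DataFrame(rows)


def calibration_sweep(dataset: MultimodalDataset, fold: SplitPlan, fractions,
                      conditions=("noneeg", "cwgan-gp", "real"),
                      gan_config: TrainConfig | None = None,
                      clf_config: ClassifierConfig | None = None,
                      seed: int = 0, models: dict | None = None) -> CalibrationResult:
    """Accuracy as a function of the calibration fraction used.

    For each fraction f in (0, 1), the chronological prefix of the fold's
    calibration portion (f of its rows) trains the classifiers (and feeds
    synthesis); the remainder of the calibration portion is the test set, so
    the saving in calibration time is measured on held-back calibration data.
    The fold's GAN is trained once per variant and reused across fractions.
    """
    fractions = sorted(float(f) for f in fractions)
    if any(not 0.0 < f < 1.0 for f in fractions):
        raise ValueError("fractions must lie strictly in (0, 1); "
                         "1.0 leaves no test rows")
    models = dict(models or {})
    for cond in conditions:
        if cond in VARIANTS and cond not in models:
            models[cond] = train_fold_gan(
                dataset, fold, cond, gan_config or TrainConfig(seed=seed))
    n_classes = dataset.schema.label_scheme.n_classes
    curves: dict[str, dict[float, float]] = {c: {} for c in conditions}
    cal = fold.cal_idx
    for f in fractions:
        n_train = int(math.ceil(f * cal.size))
        train_rows, test_rows = cal[:n_train], cal[n_train:]
        if np.unique(dataset.y[train_rows]).size < 2 or test_rows.size == 0:
            warnings.warn(f"fraction {f} leaves too few rows per class; skipped")
            continue
        if np.unique(dataset.y[test_rows]).size < n_classes:
            warnings.warn(f"fraction {f}: not all classes in the test split")
        for cond in conditions:
            m = _ensemble_on_fold(dataset, fold, train_rows, test_rows, cond,
                                  models.get(cond), clf_config, seed)
            curves[cond][f] = m.mean_accuracy
    return CalibrationResult(curves=curves)


def compute_cis(A: float, B: float) -> float:
    """Calibration improvement score (1 - B/A) * 100, in percent."""
    if A <= 0:
        raise ValueError("baseline duration A must be positive")
    if B < 0:
        raise ValueError("improved duration B must be non-negative")
    return (1.0 - B / A) * 100.0


def accuracy_ratio(condition_accuracy: float,
                   reference_accuracy: float) -> tuple[float, int]:
    """Accuracy of a condition as a percentage of a reference condition.

    Returns the unrounded percentage and its integer rounding.
    """
    if reference_accuracy <= 0:
        raise ValueError("reference accuracy must be positive")
    pct = 100.0 * condition_accuracy / reference_accuracy
    return float(pct), int(round(pct))
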