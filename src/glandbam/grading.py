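"""SVM grading of tissue images from aberrance features.

Two tasks mirror clinical practice: a two-class split (normal vs cancer,
with low- and high-grade tumour images merged into one cancer class) and a
three-class split (normal vs low grade vs high grade).  Feature Set 1 is
{mean BAM, BAM entropy}; Feature Set 2 adds the Regularity Index.

Evaluation is repeated stratified k-fold cross-validation (default 3 folds,
10 repeats): features are standardized with training-fold statistics, an
RBF-kernel support-vector classifier is fit, and accuracy plus per-class
precision / recall / specificity / F1 are averaged over fold x repeat runs
(reported as mean +/- sd).  One-vs-rest decision scores pooled over folds
give ROC curves and AUCs.  The three-class predictions can additionally be
collapsed into two binary views ("Cancer" = low+high positive, "High
grade" = high positive) for per-category metrics, and a Kruskal-Wallis test
checks whether a feature separates the grade groups at all.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import InvalidInputError, SchemaError, UndefinedFeatureError

__all__ = [
    "GradingConfig",
    "EvalReport",
    "FEATURE_SETS",
    "GRADE_ORDER",
    "train_grader",
    "cross_validate",
    "evaluate_binary_views",
    "roc_analysis",
    "kruskal_wallis",
]

FEATURE_SETS = {
    "fs1": ["mean_bam", "bam_entropy"],
    "fs2": ["mean_bam", "bam_entropy", "regularity_index"],
}
GRADE_ORDER = ["normal", "low_grade", "high_grade"]


@dataclass(frozen=True)
class GradingConfig:
    """Classifier and cross-validation settings.

    ``gamma='auto'`` means 1 / (n_features * pooled feature variance)
    (sklearn's 'scale'); after standardization this is ~1/n_features.
    """

    task: str = "three_class"
    feature_set: str = "fs2"
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "auto"
    folds: int = 3
    repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("two_class", "three_class"):
            raise InvalidInputError(f"unknown task {self.task!r}")
        if self.feature_set not in FEATURE_SETS:
            raise InvalidInputError(f"unknown feature set {self.feature_set!r}")
        if self.kernel not in ("linear", "poly", "polynomial", "rbf", "sigmoid"):
            raise InvalidInputError(f"unknown kernel {self.kernel!r}")
        if self.folds < 2:
            raise InvalidInputError("need folds >= 2")
        if self.repeats < 1:
            raise InvalidInputError("need repeats >= 1")
        if self.C <= 0:
            raise InvalidInputError("C must be positive")

    @property
    def feature_columns(self) -> list[str]:
        return FEATURE_SETS[self.feature_set]


@dataclass
class EvalReport:
    """Cross-validation summary: mean +/- sd metrics, confusion matrix, ROC.

    Rates are stored as fractions in [0, 1]; :meth:`to_dict` optionally
    reports them as percentages.  ``confusion`` is summed over all fold x
    repeat runs, so its total equals n_images * repeats.
    """

    classes: list[str]
    accuracy_mean: float
    accuracy_std: float
    per_class: dict[str, dict[str, tuple[float, float]]]
    confusion: np.ndarray
    roc: dict[str, dict] = field(default_factory=dict)

    def to_dict(self, percent: bool = True) -> dict:
        scale = 100.0 if percent else 1.0
        out = {
            "classes": list(self.classes),
            "accuracy_mean": self.accuracy_mean * scale,
            "accuracy_std": self.accuracy_std * scale,
            "per_class": {
                cls: {m: [v[0] * scale, v[1] * scale] for m, v in metrics.items()}
                for cls, metrics in self.per_class.items()
            },
            "confusion_matrix": self.confusion.tolist(),
            "auc": {cls: r["auc"] for cls, r in self.roc.items()},
        }
        return out


def _extract_xy(features: pd.DataFrame, labels, cfg: GradingConfig):
    """Feature matrix and label vector for the configured task."""
    cols = cfg.feature_columns
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns {missing}")
    if labels is None:
        if "label" not in features.columns:
            raise SchemaError("no labels given and feature table has no 'label' column")
        labels = features["label"]
    y = np.asarray(labels, dtype=object)
    known = np.isin(y, GRADE_ORDER)
    if not known.all():
        bad = sorted(set(y[~known]))
        raise SchemaError(f"unknown grade labels {bad}; expected one of {GRADE_ORDER}")
    X = features.loc[:, cols].to_numpy(dtype=float)
    X, y = X[known], y[known]
    if cfg.task == "two_class":
        y = np.where(y == "normal", "normal", "cancer")
    classes = [c for c in (["normal", "cancer"] if cfg.task == "two_class" else GRADE_ORDER)
               if c in set(y)]
    return X, y, classes


def _make_pipeline(cfg: GradingConfig) -> Pipeline:
    gamma = "scale" if cfg.gamma == "auto" else cfg.gamma
    kernel = "poly" if cfg.kernel == "polynomial" else cfg.kernel
    svc = SVC(
        kernel=kernel, C=cfg.C, gamma=gamma,
        decision_function_shape="ovr", random_state=cfg.seed,
    )
    return Pipeline([("scale", StandardScaler()), ("svm", svc)])


def train_grader(features: pd.DataFrame, labels=None, cfg: GradingConfig = GradingConfig()):
    """Fit the standardize-then-SVM pipeline on a full feature table.

    Returns the fitted sklearn :class:`~sklearn.pipeline.Pipeline`; the
    scaler inside it stores the training statistics, so held-out data passed
    to ``predict`` is standardized consistently.
    """
    X, y, classes = _extract_xy(features, labels, cfg)
    if len(classes) < 2:
        raise InvalidInputError("training needs at least 2 classes present")
    model = _make_pipeline(cfg)
    model.fit(X, y)
    return model


def _binary_rates(y_true01: np.ndarray, y_pred01: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y_true01 == 1) & (y_pred01 == 1)))
    tn = int(np.sum((y_true01 == 0) & (y_pred01 == 0)))
    fp = int(np.sum((y_true01 == 0) & (y_pred01 == 1)))
    fn = int(np.sum((y_true01 == 1) & (y_pred01 == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(y_true01)
    return {
        "accuracy": accuracy, "precision": precision, "recall": recall,
        "specificity": specificity, "f1": f1,
    }


def _summarize(fold_metrics: dict) -> dict:
    return {m: (float(np.mean(v)), float(np.std(v))) for m, v in fold_metrics.items()}


def cross_validate(
    features: pd.DataFrame, labels=None, cfg: GradingConfig = GradingConfig()
) -> EvalReport:
    """Repeated stratified k-fold cross-validation of the grading SVM.

    Every repeat reshuffles the fold assignment (seeded); metrics are
    averaged over all fold x repeat runs.  Decision scores of held-out
    samples are pooled across folds to produce one ROC curve and AUC per
    class (one-vs-rest).
    """
    X, y, classes = _extract_xy(features, labels, cfg)
    if len(classes) < 2:
        raise InvalidInputError("cross-validation needs at least 2 classes")
    counts = {c: int(np.sum(y == c)) for c in classes}
    for c, n_c in counts.items():
        if n_c < cfg.folds:
            raise InvalidInputError(
                f"class {c!r} has only {n_c} samples for {cfg.folds}-fold CV"
            )
    accs: list[float] = []
    per_class_folds: dict[str, dict[str, list[float]]] = {
        c: defaultdict(list) for c in classes
    }
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    cls_index = {c: i for i, c in enumerate(classes)}
    pooled_scores: dict[str, list] = {c: [] for c in classes}
    pooled_truth: dict[str, list] = {c: [] for c in classes}
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []

    for rep in range(cfg.repeats):
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed + rep)
        for train_idx, test_idx in skf.split(X, y):
            model = _make_pipeline(cfg)
            model.fit(X[train_idx], y[train_idx])
            y_pred = model.predict(X[test_idx])
            y_test = y[test_idx]
            scores = model.decision_function(X[test_idx])
            model_classes = list(model.classes_)
            accs.append(float(np.mean(y_pred == y_test)))
            for c in classes:
                rates = _binary_rates((y_test == c).astype(int), (y_pred == c).astype(int))
                for m, v in rates.items():
                    per_class_folds[c][m].append(v)
            for t, p in zip(y_test, y_pred):
                confusion[cls_index[t], cls_index[p]] += 1
            if scores.ndim == 1:  # binary: score for the second class
                score_map = {model_classes[1]: scores, model_classes[0]: -scores}
            else:
                score_map = {c: scores[:, model_classes.index(c)] for c in model_classes}
            for c in classes:
                pooled_scores[c].extend(score_map[c])
                pooled_truth[c].extend((y_test == c).astype(int))
            y_true_all.append(y_test)
            y_pred_all.append(y_pred)

    roc = {}
    for c in classes:
        truth = np.array(pooled_truth[c])
        if truth.min() != truth.max():
            fpr, tpr, auc_val = roc_analysis(np.array(pooled_scores[c]), truth)
            roc[c] = {"fpr": fpr, "tpr": tpr, "auc": auc_val}
    report = EvalReport(
        classes=classes,
        accuracy_mean=float(np.mean(accs)),
        accuracy_std=float(np.std(accs)),
        per_class={c: _summarize(per_class_folds[c]) for c in classes},
        confusion=confusion,
        roc=roc,
    )
    # stash raw fold predictions so binary views can be derived afterwards
    report._fold_predictions = (y_true_all, y_pred_all)  # type: ignore[attr-defined]
    return report


BINARY_VIEWS = {
    "cancer": {"low_grade", "high_grade"},
    "high_grade": {"high_grade"},
}


def evaluate_binary_views(report: EvalReport) -> dict[str, dict[str, tuple[float, float]]]:
    """Collapse three-class CV predictions into the two binary categories.

    "cancer" treats low and high grade as positive; "high_grade" treats
    normal and low grade as negative.  Returns mean +/- sd of accuracy,
    precision, recall, specificity and F1 per view across fold runs.
    """
    preds = getattr(report, "_fold_predictions", None)
    if preds is None:
        raise InvalidInputError("report carries no fold predictions; run cross_validate first")
    y_true_all, y_pred_all = preds
    views: dict[str, dict[str, tuple[float, float]]] = {}
    for view, positive in BINARY_VIEWS.items():
        folds: dict[str, list[float]] = defaultdict(list)
        for y_t, y_p in zip(y_true_all, y_pred_all):
            t01 = np.isin(y_t, list(positive)).astype(int)
            p01 = np.isin(y_p, list(positive)).astype(int)
            for m, v in _binary_rates(t01, p01).items():
                folds[m].append(v)
        views[view] = _summarize(folds)
    return views


def grid_search_hyperparameters(
    features: pd.DataFrame,
    labels=None,
    cfg: GradingConfig = GradingConfig(),
    C_grid=(0.1, 1.0, 10.0, 100.0),
    gamma_grid=(0.01, 0.1, 1.0, 10.0),
) -> GradingConfig:
    """Pick (C, gamma) by inner cross-validation accuracy.

    Off by default everywhere — the pipeline's defaults are deliberate and
    deterministic — but available for sensitivity experiments.  Returns a
    copy of ``cfg`` with the winning hyperparameters (ties: first grid
    entry, i.e. the least complex model encountered).
    """
    from dataclasses import replace as _replace

    best = (-np.inf, cfg.C, cfg.gamma)
    for C in C_grid:
        for gamma in gamma_grid:
            trial = _replace(cfg, C=C, gamma=gamma)
            acc = cross_validate(features, labels, trial).accuracy_mean
            if acc > best[0]:
                best = (acc, C, gamma)
    return _replace(cfg, C=best[1], gamma=best[2])


def roc_analysis(scores, labels, positive_label=1) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR) and trapezoidal AUC for one-vs-rest scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    truth = (labels == positive_label).astype(int)
    if truth.min() == truth.max():
        raise UndefinedFeatureError("ROC undefined: labels contain a single class")
    fpr, tpr, _ = _sk_roc_curve(truth, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups of values.

    Returns (H, p) with tie correction and the chi-square approximation on
    len(groups) - 1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise InvalidInputError("groups must be non-empty")
    if sum(len(g) for g in groups) < 3:
        raise InvalidInputError("need at least 3 values in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise InvalidInputError("degenerate test: all values identical")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
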