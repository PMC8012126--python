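"""Classifier training, Se/Sp/F1/AUC/ACC reporting and per-feature rank tests.

Five standard classifiers are supported — RBF support vector machine (svm),
random forest (rf), Gaussian naive Bayes (nb), k-nearest neighbours (knn) and
a decision tree (dt) — each behind a training-set-standardized pipeline.  The
target (ILFS) state is the positive class, so sensitivity measures how well
the impulse itself is detected.  Metrics are computed from confusion counts
pooled over CV folds (fold-wise values are reported alongside); AUC is the
rank-based (Mann-Whitney) area computed from the continuous scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset_builder import LabeledDataset
from .exceptions import InvalidParameterError
from .feature_selection import nested_cv
from .hrv_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("svm", "rf", "nb", "knn", "dt")

#: fixed default hyperparameters (all overridable per call)
DEFAULT_PARAMS: dict[str, dict] = {
    "svm": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
    "rf": {"n_estimators": 100},
    "nb": {},
    "knn": {"n_neighbors": 5},
    "dt": {"criterion": "gini"},
}


def make_classifier(name: str, seed: int = 0, classifier_params: dict | None = None) -> Pipeline:
    """Standardization + classifier pipeline for one of the five names."""
    if name not in CLASSIFIER_NAMES:
        raise InvalidParameterError(
            f"unknown classifier {name!r}; valid names: {', '.join(CLASSIFIER_NAMES)}"
        )
    params = {**DEFAULT_PARAMS[name], **(classifier_params or {})}
    if name == "svm":
        est = SVC(random_state=seed, **params)
    elif name == "rf":
        est = RandomForestClassifier(random_state=seed, **params)
    elif name == "nb":
        est = GaussianNB(**params)
    elif name == "knn":
        est = KNeighborsClassifier(**params)
    else:
        est = DecisionTreeClassifier(random_state=seed, **params)
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    classifier: str,
    seed: int = 0,
    classifier_params: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one classifier and return hard labels and continuous scores.

    Features are standardized with training-set statistics only.  Scores are
    class-1 probabilities where available, otherwise the decision margin.
    """
    if len(np.unique(y_train)) < 2:
        raise InvalidParameterError("training data must contain both classes")
    pipe = make_classifier(classifier, seed, classifier_params)
    pipe.fit(X_train, y_train)
    labels = pipe.predict(X_test)
    if hasattr(pipe, "predict_proba") and hasattr(pipe[-1], "predict_proba"):
        scores = pipe.predict_proba(X_test)[:, 1]
    else:
        scores = pipe.decision_function(X_test)
    return np.asarray(labels, dtype=int), np.asarray(scores, dtype=float)


@dataclass
class MetricReport:
    """Confusion counts and the derived Se/Sp/F1/AUC/ACC for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    se: float
    sp: float
    f1: float
    auc: float
    acc: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("se", "sp", "f1", "auc", "acc",
                                              "tp", "fp", "tn", "fn")}


def compute_metrics(y_true: np.ndarray, labels: np.ndarray, scores: np.ndarray) -> MetricReport:
    """Se/Sp/F1/ACC from the confusion table, AUC from the score ranks."""
    y_true = np.asarray(y_true, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise InvalidParameterError("y_true must contain both classes")
    tp = int(np.sum((y_true == 1) & (labels == 1)))
    fn = int(np.sum((y_true == 1) & (labels == 0)))
    tn = int(np.sum((y_true == 0) & (labels == 0)))
    fp = int(np.sum((y_true == 0) & (labels == 1)))
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + fp + tn + fn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    f1 = (2 * precision * se / (precision + se)) if precision + se > 0 else 0.0
    auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    return MetricReport(tp=tp, fp=fp, tn=tn, fn=fn,
                        se=se, sp=sp, f1=f1, auc=auc, acc=acc)


def feature_analysis(
    X_ilfs: np.ndarray,
    X_non: np.ndarray,
    paired: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-group rank test between the two states.

    The groups are unpaired trials, so the primary test is the two-sided
    rank-sum (Mann-Whitney) test; ``paired=True`` switches to the
    signed-rank variant for matched designs.  The report carries the p-value,
    a significance flag at ``alpha`` and the direction of the median
    difference (positive = larger in the target state).
    """
    X_ilfs = np.atleast_2d(np.asarray(X_ilfs, dtype=float))
    X_non = np.atleast_2d(np.asarray(X_non, dtype=float))
    if X_ilfs.shape[0] < 5 or X_non.shape[0] < 5:
        raise InvalidParameterError("need >= 5 observations per group")
    rows = []
    for i, name in enumerate(FEATURE_NAMES):
        a, b = X_ilfs[:, i], X_non[:, i]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        combined = np.concatenate([a, b])
        if len(a) < 5 or len(b) < 5 or np.all(combined == combined[0]):
            if len(a) >= 5 and len(b) >= 5:
                logger.warning("feature %s: all values tied; p = 1", name)
            p = 1.0
        elif paired:
            d = a[: min(len(a), len(b))] - b[: min(len(a), len(b))]
            p = 1.0 if np.all(d == 0) else float(stats.wilcoxon(d).pvalue)
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        direction = float(np.median(a) - np.median(b)) if len(a) and len(b) else np.nan
        rows.append({
            "feature": i + 1,
            "name": name,
            "p_value": p,
            "significant": p < alpha,
            "median_diff": direction,
        })
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Per-classifier pooled metrics plus fold detail for one experiment."""

    mode: str
    pooled: dict[str, MetricReport] = field(default_factory=dict)
    fold_metrics: dict[str, list[MetricReport]] = field(default_factory=dict)
    selected_subsets: dict[str, list[tuple[int, ...]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.pooled.items():
            rows.append({"classifier": name, "Se": m.se, "Sp": m.sp,
                         "F1": m.f1, "AUC": m.auc, "ACC": m.acc})
        return pd.DataFrame(rows)


def run_experiment(
    dataset: LabeledDataset,
    mode: str = "without",
    seed: int = 0,
    classifiers=CLASSIFIER_NAMES,
    k_max: int | None = None,
    folds: int = 10,
    classifier_params: dict[str, dict] | None = None,
) -> EvalReport:
    """Score the five classifiers with plain (``mode='without'``) or nested,
    selection-inside (``mode='with'``) stratified 10-fold cross-validation.

    Confusion counts are pooled over the (outer) folds before computing the
    headline metrics; per-fold metrics are kept for dispersion estimates.
    """
    if mode not in ("with", "without"):
        raise InvalidParameterError("mode must be 'with' or 'without'")
    X, y = dataset.X, dataset.y
    report = EvalReport(mode=mode)
    params = classifier_params or {}
    for name in classifiers:
        y_all, pred_all, score_all = [], [], []
        fold_metrics: list[MetricReport] = []
        if mode == "without":
            n_folds = min(folds, int(np.min(np.bincount(y))))
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            for train, test in skf.split(X, y):
                labels, scores = fit_predict(
                    X[train], y[train], X[test], name, seed, params.get(name)
                )
                y_all.append(y[test]); pred_all.append(labels); score_all.append(scores)
        else:
            folds_out = nested_cv(
                X, y, name, k_max=k_max, seed=seed, outer_folds=folds,
                inner_folds=folds, classifier_params=params.get(name),
            )
            report.selected_subsets[name] = [f.subset for f in folds_out]
            for f in folds_out:
                y_all.append(f.y_true); pred_all.append(f.y_pred); score_all.append(f.scores)
        for yt, yp, sc in zip(y_all, pred_all, score_all):
            if len(np.unique(yt)) == 2:
                fold_metrics.append(compute_metrics(yt, yp, sc))
        report.pooled[name] = compute_metrics(
            np.concatenate(y_all), np.concatenate(pred_all), np.concatenate(score_all)
        )
        report.fold_metrics[name] = fold_metrics
    return report
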