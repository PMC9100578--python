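"""Predictive-analysis harness: repeated stratified CV of a pluggable
classifier, confusion-matrix metrics, feature-importance aggregation and
the incremental top-k feature experiment.

The classifier is an opaque factory returning a scikit-learn style
estimator (``fit`` / ``predict`` / optionally ``predict_proba`` and
``feature_importances_``). The reference backend is a gradient-boosted
tree learner that tolerates missing values natively, matching the
no-imputation policy of the data model. The harness, not the learner, is
the subject here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from .data_model import DecisionProblem, ImmunoDataset
from .trees import ConfusionMatrix, kappa

__all__ = [
    "f1",
    "metrics",
    "confusion_from_predictions",
    "CVResult",
    "repeated_stratified_cv",
    "gbm_factory",
    "majority_factory",
    "rank_average_importance",
    "permutation_importance",
    "incremental_feature_experiment",
    "roc_points",
    "roc_auc",
]

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1",
                "accuracy", "kappa")


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision (PPV) and sensitivity (TPR); 0 if TP = 0."""
    if cm.tp == 0:
        return 0.0
    ppv = cm.tp / (cm.tp + cm.fp)
    tpr = cm.tp / (cm.tp + cm.fn)
    return 2.0 * ppv * tpr / (ppv + tpr)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Standard confusion-matrix metrics; zero-denominator cases are NaN."""
    out = {
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "ppv": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "f1": f1(cm),
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
    }
    try:
        out["kappa"] = kappa(cm)
    except ValueError:
        out["kappa"] = math.nan
    return out


def confusion_from_predictions(y_true: np.ndarray,
                               y_pred: np.ndarray) -> ConfusionMatrix:
    """Confusion counts of boolean (primary-class) labels and predictions."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    return ConfusionMatrix(
        tp=int((y_pred & y_true).sum()),
        tn=int((~y_pred & ~y_true).sum()),
        fp=int((y_pred & ~y_true).sum()),
        fn=int((~y_pred & y_true).sum()),
    )


@dataclass
class CVResult:
    """All per-fold artefacts of one repeated-CV run."""

    problem_id: str
    k: int
    reps: int
    seed: int
    features: list[str]
    confusions: list[ConfusionMatrix] = field(default_factory=list)
    fold_metrics: pd.DataFrame | None = None
    rankings: list[list[str]] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean and sd of each metric across folds (NaN folds excluded)."""
        means = self.fold_metrics.mean(skipna=True)
        sds = self.fold_metrics.std(skipna=True, ddof=1)
        excluded = self.fold_metrics.isna().sum()
        return pd.DataFrame({"mean": means, "sd": sds,
                             "n_excluded_folds": excluded})

    def pooled_confusion(self) -> ConfusionMatrix:
        return ConfusionMatrix(
            tp=sum(c.tp for c in self.confusions),
            tn=sum(c.tn for c in self.confusions),
            fp=sum(c.fp for c in self.confusions),
            fn=sum(c.fn for c in self.confusions),
        )

    def pooled_metrics(self) -> dict[str, float]:
        return metrics(self.pooled_confusion())


def gbm_factory(seed: int = 0, **kw):
    """Factory for the reference gradient-boosted-tree backend.

    LightGBM handles missing values natively, so no imputation happens
    anywhere in the pipeline.
    """
    from lightgbm import LGBMClassifier

    defaults = dict(n_estimators=100, max_depth=4, verbose=-1,
                    random_state=seed, n_jobs=1, importance_type="gain")
    defaults.update(kw)

    def make():
        return LGBMClassifier(**defaults)

    return make


def majority_factory():
    """Factory for a majority-class dummy (closed-form CV baseline)."""
    from sklearn.dummy import DummyClassifier

    def make():
        return DummyClassifier(strategy="most_frequent")

    return make


def _problem_arrays(ds: ImmunoDataset, problem: DecisionProblem,
                    features: list[str] | None):
    feats = list(features) if features is not None else ds.marker_names
    assigned = problem.assigned
    X = ds.values.loc[assigned, feats].to_numpy(float)
    y = (problem.y.loc[assigned] == 1).to_numpy()
    return X, y, feats


def _ranking_from_model(model, feats: list[str]) -> list[str] | None:
    imp = getattr(model, "feature_importances_", None)
    if imp is None:
        return None
    order = sorted(range(len(feats)), key=lambda i: (-imp[i], feats[i]))
    return [feats[i] for i in order]


def repeated_stratified_cv(ds: ImmunoDataset, problem: DecisionProblem,
                           model_factory, k: int = 5, reps: int = 10,
                           seed: int = 0,
                           features: list[str] | None = None) -> CVResult:
    """Stratified k-fold cross-validation repeated ``reps`` times.

    Folds preserve class proportions; every repetition reshuffles
    deterministically from the master ``seed``; k*reps models are built
    and every held-out confusion matrix is retained. Raises if either
    class has fewer than ``k`` members.
    """
    X, y, feats = _problem_arrays(ds, problem, features)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"smallest class has {min(n_pos, n_neg)} members; need >= k={k}")
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=reps,
                                       random_state=seed)
    result = CVResult(problem.id, k, reps, seed, feats)
    rows = []
    for train_idx, test_idx in splitter.split(X, y):
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        pred = np.asarray(model.predict(X[test_idx]), dtype=bool)
        cm = confusion_from_predictions(y[test_idx], pred)
        result.confusions.append(cm)
        rows.append(metrics(cm))
        ranking = _ranking_from_model(model, feats)
        if ranking is not None:
            result.rankings.append(ranking)
    result.fold_metrics = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    return result


def rank_average_importance(rankings: list[list[str]]) -> list[tuple[str, float]]:
    """Features by mean rank position across models (1 = most important).

    All rankings must cover the same feature set; ties break by name.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    feature_set = set(rankings[0])
    for r in rankings[1:]:
        if set(r) != feature_set:
            raise ValueError("rankings cover inconsistent feature sets")
    mean_pos = {f: np.mean([r.index(f) + 1 for r in rankings])
                for f in feature_set}
    return sorted(mean_pos.items(), key=lambda kv: (kv[1], kv[0]))


def permutation_importance(model, ds: ImmunoDataset, problem: DecisionProblem,
                           metric=f1, n_permutations: int = 10, seed: int = 0,
                           features: list[str] | None = None
                           ) -> list[tuple[str, float]]:
    """Model-agnostic importance: mean metric drop under column shuffles.

    For each feature the column is permuted ``n_permutations`` times and
    the importance is the mean drop of ``metric`` (computed on the
    problem's examples) relative to the unperturbed model. Deterministic
    given ``seed``; features the model ignores score ~0.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    X, y, feats = _problem_arrays(ds, problem, features)
    rng = np.random.default_rng(seed)
    base = metric(confusion_from_predictions(y, model.predict(X)))
    scores = {}
    for j, name in enumerate(feats):
        drops = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            drops.append(base - metric(
                confusion_from_predictions(y, model.predict(Xp))))
        scores[name] = float(np.mean(drops))
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def incremental_feature_experiment(ds: ImmunoDataset, problem: DecisionProblem,
                                   ranking: list[str], model_factory,
                                   k: int = 5, reps: int = 10,
                                   seed: int = 0) -> pd.DataFrame:
    """F1 trajectory of classifiers on growing top-m feature sets.

    Runs the repeated CV restricted to the top-m ranked features for
    m = 1..len(ranking) with identical fold seeds, so the final entry
    reproduces the unrestricted run on the same feature order.
    """
    if not ranking:
        raise ValueError("ranking must be non-empty")
    rows = []
    for m in range(1, len(ranking) + 1):
        res = repeated_stratified_cv(ds, problem, model_factory, k=k,
                                     reps=reps, seed=seed,
                                     features=ranking[:m])
        rows.append({"n_features": m,
                     "f1_mean": res.fold_metrics["f1"].mean(),
                     "f1_sd": res.fold_metrics["f1"].std(ddof=1)})
    return pd.DataFrame(rows)


def roc_points(rep_scores: list[np.ndarray], rep_labels: list[np.ndarray],
               fpr_grid: np.ndarray | None = None) -> pd.DataFrame:
    """ROC curve with across-repetition 95% bands on a common FPR grid.

    Each (scores, labels) pair is one repetition; TPR is interpolated on
    the FPR grid per repetition and the band is mean +/- 1.96 sd. With a
    single repetition the band collapses onto the curve.
    """
    from sklearn.metrics import roc_curve

    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    for scores, labels in zip(rep_scores, rep_labels):
        labels = np.asarray(labels, dtype=bool)
        if labels.all() or not labels.any():
            raise ValueError("ROC needs both classes present")
        fpr, tpr, _ = roc_curve(labels, scores)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    tprs = np.vstack(tprs)
    mean = tprs.mean(axis=0)
    sd = tprs.std(axis=0, ddof=1) if len(tprs) > 1 else np.zeros_like(mean)
    return pd.DataFrame({"fpr": fpr_grid, "tpr_mean": mean,
                         "tpr_lo": np.clip(mean - 1.96 * sd, 0, 1),
                         "tpr_hi": np.clip(mean + 1.96 * sd, 0, 1)})


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of one score vector."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    return float(roc_auc_score(labels, scores))
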