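"""Subject-level classification: wide feature table, exactly-k LASSO
selection, and leave-one-out cross-validation over four model families.

The feature table has exactly one row per subject — per-trial features are
spread into (feature, trial) columns — so a subject can never appear in
both a training fold and its own test fold.  Inside every LOOCV fold the
scaler, the L1-penalised logistic selection (tuned by bisection on the
penalty so that exactly k = 10 columns survive) and the classifier are all
re-fit on the training subjects only; the held-out subject contributes one
hard prediction and one continuous score.  Classifiers are fit with
balanced per-fold sample weights: every leave-one-out training fold is
slightly class-imbalanced, which would otherwise bias pooled null scores
below chance.  Accuracy and F1 are computed
from the pooled hard predictions, AUROC and AUCPR from the pooled scores
(per-fold curves are undefined with a single test sample).

Model families: an RBF-kernel support-vector machine, extremely randomised
trees, and two gradient-boosted tree variants (XGBoost and LightGBM), all
with fixed, documented hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             roc_auc_score)
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_FAMILIES, FEATURE_NAMES

__all__ = [
    "FeatureTable",
    "CVReport",
    "MODEL_FAMILIES",
    "FEATURE_SETS",
    "build_feature_table",
    "lasso_select",
    "make_model",
    "loocv_evaluate",
    "evaluate_feature_sets",
]

MODEL_FAMILIES = ("svm", "extra_trees", "xgboost", "lightgbm")
FEATURE_SETS = ("saccadic", "fixation", "scanpath", "multi_type")


@dataclass
class FeatureTable:
    """Subjects x (feature, trial) matrix with binary labels (1 = case)."""

    X: pd.DataFrame             # index = subject_id, columns = "feature__tNN"
    y: np.ndarray               # 0/1 per subject
    missing_mask: pd.DataFrame  # True where a cell was imputed

    @property
    def subjects(self) -> list[str]:
        return list(self.X.index)


def _family_features(feature_set: str) -> list[str]:
    if feature_set == "multi_type":
        return list(FEATURE_NAMES)
    if feature_set not in FEATURE_FAMILIES:
        raise ValueError(f"unknown feature set {feature_set!r}")
    return list(FEATURE_FAMILIES[feature_set])


def build_feature_table(
    features: pd.DataFrame,
    groups: dict[str, str],
    case_label: str,
    n_trials: int,
    feature_set: str = "multi_type",
) -> FeatureTable:
    """Pivot per-trial features into one wide row per subject.

    Trials are ranked per subject in presentation order; a subject with
    fewer than ``n_trials`` retained trials has the missing cells filled
    with that subject's own median of the feature (never with other
    subjects' data).  Subjects with zero retained trials are excluded.
    Column order is deterministic: feature-major, trial-minor.
    """
    names = _family_features(feature_set)
    df = features.copy()
    df["_rank"] = df.groupby("subject_id")["trial_id"].rank(method="first").astype(int)
    df = df[df["_rank"] <= n_trials]

    subjects = sorted(df["subject_id"].unique())
    columns = [f"{name}__t{r:02d}" for name in names for r in range(1, n_trials + 1)]
    X = pd.DataFrame(np.nan, index=subjects, columns=columns)
    for _, row in df.iterrows():
        for name in names:
            X.loc[row["subject_id"], f"{name}__t{row['_rank']:02d}"] = row[name]

    missing = X.isna()
    for name in names:
        cols = [c for c in columns if c.startswith(f"{name}__")]
        med = X[cols].median(axis=1)
        for c in cols:
            X[c] = X[c].fillna(med)
    # a feature missing in every trial for a subject (e.g. no saccades at
    # all) falls back to the column median across subjects
    X = X.fillna(X.median())

    y = np.array([1 if groups[s] == case_label else 0 for s in subjects])
    return FeatureTable(X=X, y=y, missing_mask=missing)


def lasso_select(X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0,
                 max_iter_bisect: int = 40) -> tuple[np.ndarray, bool]:
    """Column indices of an exactly-k L1-logistic selection.

    The inverse penalty C is bisected until exactly k coefficients are
    nonzero; if a plateau makes k unattainable, the largest achievable
    count below k is returned and flagged.  Standardise X before calling
    (fit the scaler on training data only).  Returns (indices, exact_k).
    """
    n_features = X.shape[1]
    if n_features <= k:
        return np.arange(n_features), False

    def nnz(c: float) -> tuple[int, np.ndarray]:
        model = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                   random_state=seed, max_iter=1000)
        model.fit(X, y)
        coef = model.coef_.ravel()
        return int(np.sum(coef != 0)), coef

    lo, hi = 1e-4, 1e4
    n_hi, coef_hi = nnz(hi)
    if n_hi <= k:
        idx = np.flatnonzero(coef_hi)
        return idx, n_hi == k
    best_idx, best_n = np.flatnonzero(coef_hi)[:0], 0
    for _ in range(max_iter_bisect):
        mid = np.sqrt(lo * hi)
        n_mid, coef_mid = nnz(mid)
        if n_mid == k:
            return np.flatnonzero(coef_mid), True
        if best_n < n_mid < k or (n_mid < k and best_n == 0):
            best_n, best_idx = n_mid, np.flatnonzero(coef_mid)
        if n_mid < k:
            lo = mid
        else:
            hi = mid
    if best_n == 0:
        # plateau jumped over k entirely; take the top-|coef| k at hi
        order = np.argsort(-np.abs(coef_hi))
        return np.sort(order[:k]), False
    return best_idx, False


def make_model(family: str, seed: int = 0):
    """Classifier with fixed hyperparameters for one model family."""
    if family == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if family == "extra_trees":
        return ExtraTreesClassifier(n_estimators=200, random_state=seed)
    if family == "xgboost":
        from xgboost import XGBClassifier
        # min_child_weight below the logloss-hessian of a handful of
        # samples, so splits are possible at clinical-cohort fold sizes
        return XGBClassifier(n_estimators=150, max_depth=3, learning_rate=0.1,
                             min_child_weight=0.5, random_state=seed,
                             verbosity=0, eval_metric="logloss")
    if family == "lightgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(n_estimators=150, max_depth=3, learning_rate=0.1,
                              random_state=seed, verbose=-1, min_child_samples=3,
                              min_sum_hessian_in_leaf=0.5)
    raise ValueError(f"unknown model family {family!r}; options: {MODEL_FAMILIES}")


def _score(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class CVReport:
    model: str
    feature_set: str
    accuracy: float   # percent
    f1: float         # percent
    auroc: float
    aucpr: float
    subjects: list[str] = field(default_factory=list)
    y_true: np.ndarray = field(default_factory=lambda: np.array([]))
    y_pred: np.ndarray = field(default_factory=lambda: np.array([]))
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    selected_counts: list[int] = field(default_factory=list)
    selected_indices: list[tuple] = field(default_factory=list)  # per fold

    def to_dict(self) -> dict:
        return {"model": self.model, "feature_set": self.feature_set,
                "accuracy": self.accuracy, "f1": self.f1,
                "auroc": self.auroc, "aucpr": self.aucpr,
                "n_folds": len(self.y_true)}


def loocv_evaluate(
    table: FeatureTable,
    model_family: str = "svm",
    k: int = 10,
    seed: int = 0,
    global_selection: bool = False,
) -> CVReport:
    """Leave-one-subject-out evaluation with per-fold selection and scaling.

    ``global_selection=True`` reproduces the leaky variant in which the
    LASSO selection is fit once on all subjects before cross-validation;
    the default re-fits everything inside each fold.
    """
    X_all = table.X.to_numpy(dtype=float)
    y_all = table.y
    n = len(y_all)
    if min(np.sum(y_all == 0), np.sum(y_all == 1)) < 2:
        raise ValueError("need at least 2 subjects per class")

    global_idx = None
    if global_selection:
        scaler = StandardScaler().fit(X_all)
        global_idx, _ = lasso_select(scaler.transform(X_all), y_all, k=k, seed=seed)

    y_pred = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    selected_counts = []
    selected_indices = []
    for i in range(n):
        train = np.arange(n) != i
        y_train = y_all[train]
        if len(np.unique(y_train)) < 2:
            y_pred[i], scores[i] = -1, np.nan  # degenerate fold, flagged
            continue
        scaler = StandardScaler().fit(X_all[train])
        X_train = scaler.transform(X_all[train])
        X_test = scaler.transform(X_all[i:i + 1])
        idx = global_idx if global_idx is not None else lasso_select(
            X_train, y_train, k=k, seed=seed)[0]
        selected_counts.append(len(idx))
        selected_indices.append(tuple(int(i) for i in idx))
        model = make_model(model_family, seed=seed)
        # balanced per-fold sample weights: leave-one-out folds are always
        # slightly imbalanced (and the cohorts themselves may be), which
        # otherwise tilts scores toward the majority class and biases the
        # pooled null AUROC below 0.5
        n_tr = len(y_train)
        n_pos = int(y_train.sum())
        w = np.where(y_train == 1, n_tr / (2.0 * n_pos), n_tr / (2.0 * (n_tr - n_pos)))
        model.fit(X_train[:, idx], y_train, sample_weight=w)
        y_pred[i] = int(model.predict(X_test[:, idx])[0])
        scores[i] = float(_score(model, X_test[:, idx])[0])

    ok = y_pred >= 0
    acc = accuracy_score(y_all[ok], y_pred[ok]) * 100.0
    f1 = f1_score(y_all[ok], y_pred[ok], zero_division=0) * 100.0
    if len(np.unique(y_all[ok])) == 2:
        auroc = roc_auc_score(y_all[ok], scores[ok])
        aucpr = average_precision_score(y_all[ok], scores[ok])
    else:
        auroc = aucpr = float("nan")
    return CVReport(model=model_family, feature_set="", accuracy=float(acc),
                    f1=float(f1), auroc=float(auroc), aucpr=float(aucpr),
                    subjects=table.subjects, y_true=y_all[ok],
                    y_pred=y_pred[ok], scores=scores[ok],
                    selected_counts=selected_counts,
                    selected_indices=selected_indices)


def evaluate_feature_sets(
    features: pd.DataFrame,
    groups: dict[str, str],
    case_label: str,
    n_trials: int,
    model_families: tuple[str, ...] = MODEL_FAMILIES,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    k: int = 10,
    seed: int = 0,
) -> list[CVReport]:
    """The full metric grid: every feature set x every model family."""
    reports = []
    for feature_set in feature_sets:
        table = build_feature_table(features, groups, case_label, n_trials, feature_set)
        for family in model_families:
            report = loocv_evaluate(table, family, k=k, seed=seed)
            report.feature_set = feature_set
            reports.append(report)
    return reports
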