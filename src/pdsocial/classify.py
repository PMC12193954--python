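"""Training, tuning and evaluation of the PD-post classifier families.

Seven model families (K-nearest neighbors, max-margin/SVM, random forest,
adaptive boosting, multinomial Naive Bayes, decision tree, gradient-boosted
trees) plus a soft-voting ensemble are tuned by grid search with stratified
5-fold cross-validation optimizing macro-averaged recall, so sensitivity is
balanced across the PD-related minority class and the irrelevant majority.
The tuned models are compared on a held-out test set with macro recall /
precision / F1 (percentile-bootstrap 95% CIs over test resamples) and ROC /
AUC, and the family with the best macro recall is selected.  Class decisions
use the fixed 0.5 probability threshold (boundary classified positive).

The hyperparameter grids are small documented defaults and can be overridden
per family.  The max-margin model is probability-calibrated so it can join
the soft-voting ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_curve,
    auc as _trapezoid_auc,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "FAMILY_ORDER",
    "default_grids",
    "split_data",
    "train_candidates",
    "build_ensemble",
    "SoftVotingEnsemble",
    "evaluate",
    "select_model",
    "predict",
    "Candidate",
    "ModelReport",
]

#: Canonical family order; also the final tie-break in model selection.
FAMILY_ORDER = (
    "naive_bayes",
    "ensemble",
    "svm",
    "decision_tree",
    "random_forest",
    "xgboost",
    "knn",
    "adaboost",
)


def _make_estimator(family: str, seed: int):
    if family == "naive_bayes":
        return MultinomialNB()
    if family == "svm":
        return CalibratedClassifierCV(LinearSVC(random_state=seed, max_iter=5000), cv=3)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if family == "xgboost":
        return XGBClassifier(
            n_estimators=100,
            tree_method="hist",
            eval_metric="logloss",
            random_state=seed,
            n_jobs=1,
        )
    if family == "knn":
        return KNeighborsClassifier()
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    raise ValueError(f"unknown model family {family!r}")


def default_grids() -> dict[str, dict[str, list]]:
    """Small documented hyperparameter grids, overridable per family."""
    return {
        "naive_bayes": {"alpha": [0.1, 0.5, 1.0]},
        "svm": {"estimator__C": [0.1, 1.0, 10.0]},
        "decision_tree": {"max_depth": [4, 8, None]},
        "random_forest": {"max_depth": [8, None]},
        "xgboost": {"max_depth": [3, 6]},
        "knn": {"n_neighbors": [3, 5, 11]},
        "adaboost": {"n_estimators": [50]},
    }


def split_data(X, y, test_fraction: float = 0.2, seed: int = 0):
    """Stratified 80/20 split, deterministic under a fixed seed.

    Stratification guarantees both classes appear in the test set; this is a
    documented strengthening of a plain random split.
    """
    y = np.asarray(y)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    train_idx, test_idx = train_test_split(
        np.arange(len(y)), test_size=test_fraction, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class Candidate:
    """A tuned, refitted model family."""

    family: str
    estimator: object
    params: dict
    cv_macro_recall: float


def train_candidates(
    X,
    y,
    families: tuple[str, ...] | None = None,
    grids: dict[str, dict] | None = None,
    seed: int = 0,
    cv: int = 5,
) -> dict[str, Candidate]:
    """Grid-search each family with stratified k-fold CV on macro recall.

    The best configuration per family is refit on the full training set.
    All randomness is seeded.
    """
    y = np.asarray(y)
    if families is None:
        families = tuple(f for f in FAMILY_ORDER if f != "ensemble")
    merged = default_grids()
    if grids:
        merged.update(grids)
    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    candidates: dict[str, Candidate] = {}
    for family in families:
        search = GridSearchCV(
            _make_estimator(family, seed),
            merged[family],
            scoring="recall_macro",
            cv=folds,
            n_jobs=1,
            refit=True,
        )
        search.fit(X, y)
        candidates[family] = Candidate(
            family=family,
            estimator=search.best_estimator_,
            params=dict(search.best_params_),
            cv_macro_recall=float(search.best_score_),
        )
    return candidates


class SoftVotingEnsemble:
    """Unweighted average of member class probabilities, classified at 0.5."""

    def __init__(self, members: list):
        for member in members:
            if not hasattr(member, "predict_proba"):
                raise ValueError("every ensemble member must expose predict_proba")
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = list(members)
        self.classes_ = np.asarray(getattr(members[0], "classes_", np.array([0, 1])))

    def predict_proba(self, X) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)

    def predict(self, X) -> np.ndarray:
        # Probability exactly 0.5 is classified positive (documented tie rule).
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def build_ensemble(candidates: dict[str, Candidate]) -> Candidate:
    """Combine tuned candidates into a soft-voting ensemble."""
    members = [candidates[f].estimator for f in FAMILY_ORDER if f in candidates]
    ensemble = SoftVotingEnsemble(members)
    return Candidate(
        family="ensemble",
        estimator=ensemble,
        params={"members": [f for f in FAMILY_ORDER if f in candidates]},
        cv_macro_recall=float("nan"),
    )


@dataclass
class ModelReport:
    """Held-out evaluation of one model family."""

    family: str
    params: dict
    macro_recall: float
    macro_precision: float
    macro_f1: float
    ci_recall: tuple[float, float]
    ci_precision: tuple[float, float]
    ci_f1: tuple[float, float]
    auc: float
    roc: tuple[np.ndarray, np.ndarray] = field(repr=False, default=(None, None))
    cv_macro_recall: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": {k: (None if v is None else v) for k, v in self.params.items()},
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "ci_recall": list(self.ci_recall),
            "ci_precision": list(self.ci_precision),
            "ci_f1": list(self.ci_f1),
            "auc": self.auc,
            "cv_macro_recall": self.cv_macro_recall,
        }


def _macro_metrics(y_true, y_pred) -> tuple[float, float, float]:
    return (
        float(recall_score(y_true, y_pred, average="macro", zero_division=0)),
        float(precision_score(y_true, y_pred, average="macro", zero_division=0)),
        float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
    )


def evaluate(
    candidate: Candidate,
    X_test,
    y_test,
    B: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> ModelReport:
    """Macro metrics with percentile-bootstrap CIs, plus ROC/AUC.

    The bootstrap resamples the test set (B draws with replacement) over
    fixed predictions; models are not refit.  AUC is the trapezoid area
    under the ROC curve.
    """
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set must contain both classes")
    prob, y_pred = predict(candidate.estimator, X_test, threshold)
    recall, precision, f1 = _macro_metrics(y_test, y_pred)
    fpr, tpr, _ = roc_curve(y_test, prob)
    area = float(_trapezoid_auc(fpr, tpr))

    rng = np.random.default_rng(seed)
    n = len(y_test)
    boot = np.empty((B, 3))
    for b in range(B):
        idx = rng.integers(0, n, n)
        while len(np.unique(y_test[idx])) < 2:  # resample until both classes present
            idx = rng.integers(0, n, n)
        boot[b] = _macro_metrics(y_test[idx], y_pred[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)

    return ModelReport(
        family=candidate.family,
        params=candidate.params,
        macro_recall=recall,
        macro_precision=precision,
        macro_f1=f1,
        ci_recall=(float(lo[0]), float(hi[0])),
        ci_precision=(float(lo[1]), float(hi[1])),
        ci_f1=(float(lo[2]), float(hi[2])),
        auc=area,
        roc=(fpr, tpr),
        cv_macro_recall=candidate.cv_macro_recall,
    )


def select_model(reports: list[ModelReport]) -> ModelReport:
    """Highest macro recall; ties broken by macro F1, then family order."""
    if not reports:
        raise ValueError("no reports to select from")

    def sort_key(report: ModelReport):
        order = FAMILY_ORDER.index(report.family) if report.family in FAMILY_ORDER else len(FAMILY_ORDER)
        return (-report.macro_recall, -report.macro_f1, order)

    return min(reports, key=sort_key)


def predict(model, X, threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class probability and thresholded label (boundary positive)."""
    prob = model.predict_proba(X)
    classes = np.asarray(getattr(model, "classes_", np.array([0, 1])))
    positive_col = int(np.argmax(classes == classes.max()))
    p = prob[:, positive_col]
    return p, (p >= threshold).astype(int)
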