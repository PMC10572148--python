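"""Diagnostic classifiers for malignant pleural effusion and their
cross-validated evaluation.

Five base learners (logistic regression, random forest, Gaussian naive
Bayes, RBF-kernel SVM with calibrated probabilities, and gradient-boosted
trees) are combined by a stacked ensemble: a logistic-regression meta-model
trained on the base learners' out-of-fold predicted probabilities, so the
meta-model never sees a base prediction made on the sample being predicted.

Features for a marker panel are log(1 + concentration) for each panel
marker, plus age and a male-gender indicator; scale-sensitive learners get
a standard scaler fitted inside each training fold (the whole learner is a
Pipeline, so refitting within cross-validation keeps folds leak-free).

Evaluation follows a pooled out-of-fold protocol: stratified k-fold (k = 3
by default), out-of-fold predicted probabilities of all patients pooled
into a single score vector, from which one AUC and one sensitivity /
specificity pair (threshold 0.5 on probability, or Youden-optimal on
request) are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    GridSearchCV,
    LeaveOneOut,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBClassifier

from .markers import canonical_panel, panel_str

__all__ = [
    "BASE_LEARNER_NAMES",
    "MODEL_NAMES",
    "PerformanceRecord",
    "compute_auc",
    "sens_spec",
    "youden_threshold",
    "feature_matrix",
    "make_base_learner",
    "make_model",
    "StackingDiagnosticClassifier",
    "cross_validated_evaluate",
]

BASE_LEARNER_NAMES = ("logistic", "random_forest", "naive_bayes", "svm", "xgboost")
MODEL_NAMES = BASE_LEARNER_NAMES + ("stacking",)

#: Small hyperparameter grids for optional inner-CV tuning.
DEFAULT_GRIDS = {
    "logistic": {"clf__C": [0.1, 1.0, 10.0]},
    "random_forest": {"clf__max_depth": [3, 6, None]},
    "naive_bayes": {},
    "svm": {"clf__estimator__C": [0.5, 1.0, 4.0]},
    "xgboost": {"clf__max_depth": [2, 3], "clf__learning_rate": [0.1, 0.3]},
}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney probability estimate.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg), computed
    via midranks in O(n log n).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def sens_spec(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) calling positive when score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    sensitivity = float((pred & pos).sum() / pos.sum())
    specificity = float((~pred & ~pos).sum() / (~pos).sum())
    return sensitivity, specificity


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 over observed scores."""
    scores = np.asarray(scores, dtype=float)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(scores):
        se, sp = sens_spec(scores, labels, t)
        j = se + sp - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def feature_matrix(cohort: pd.DataFrame, panel) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and labels for one marker panel.

    Columns: log1p of each panel marker (deterministic, sorted marker order),
    then ``age`` and ``gender_male``.  Label is 1 for MPE, 0 for BPE.
    """
    panel = canonical_panel(panel)
    x = pd.DataFrame(index=cohort.index)
    for m in panel:
        x[f"log1p_{m}"] = np.log1p(cohort[m].to_numpy(dtype=float))
    x["age"] = cohort["age"].to_numpy(dtype=float)
    x["gender_male"] = (cohort["gender"] == "male").astype(float).to_numpy()
    if x.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    y = (cohort["group"] == "MPE").astype(int).to_numpy()
    return x, y


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

def make_base_learner(name: str, random_state: int | None = None) -> Pipeline:
    """One of the five base learners as a scaler + classifier pipeline."""
    if name == "logistic":
        clf = LogisticRegression(max_iter=2000)
    elif name == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=random_state)
    elif name == "naive_bayes":
        clf = GaussianNB()
    elif name == "svm":
        # sigmoid (Platt) calibration on inner training folds gives the
        # probability contract stacking needs; SVC itself has none
        clf = CalibratedClassifierCV(
            SVC(kernel="rbf"), method="sigmoid", cv=3, ensemble=False
        )
    elif name == "xgboost":
        clf = XGBClassifier(
            n_estimators=60,
            max_depth=3,
            learning_rate=0.3,
            eval_metric="logloss",
            n_jobs=1,
            random_state=random_state if random_state is not None else 0,
        )
    else:
        raise ValueError(f"unknown base learner {name!r}; choose from {BASE_LEARNER_NAMES}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


class StackingDiagnosticClassifier(ClassifierMixin, BaseEstimator):
    """Stacked ensemble of the five base learners.

    Fitting builds a meta-feature matrix of out-of-fold predicted
    probabilities — each base learner is cross-validated on the training
    data with an inner stratified split, so every training sample's
    meta-feature comes from a model that never saw it — then trains a
    logistic-regression meta-learner on those five columns and refits every
    base learner on the full training data for prediction time.

    Parameters
    ----------
    base_learners : sequence of names, default all five
        Subset of :data:`BASE_LEARNER_NAMES`.
    inner_folds : int, default 3
        Stratified folds used to build out-of-fold meta-features.
    tune_grids : dict or None
        Optional per-learner hyperparameter grids searched by inner-CV AUC
        before stacking (``DEFAULT_GRIDS`` gives a small standard search).
    random_state : int or None
        Seeds the inner splits and every stochastic learner.

    Attributes
    ----------
    base_estimators_ : dict name -> fitted pipeline
    meta_estimator_ : fitted LogisticRegression
    classes_ : ndarray of the two class labels
    """

    def __init__(
        self,
        base_learners=BASE_LEARNER_NAMES,
        inner_folds: int = 3,
        tune_grids: dict | None = None,
        random_state: int | None = None,
    ):
        self.base_learners = base_learners
        self.inner_folds = inner_folds
        self.tune_grids = tune_grids
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if counts.min() < self.inner_folds:
            raise ValueError(
                f"minority class has {counts.min()} samples; cannot stratify "
                f"{self.inner_folds} inner folds"
            )
        self.classes_ = classes
        cv = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True, random_state=self.random_state
        )

        templates = {}
        for name in self.base_learners:
            est = make_base_learner(name, random_state=self.random_state)
            grid = (self.tune_grids or {}).get(name)
            if grid:
                est = GridSearchCV(est, grid, cv=cv, scoring="roc_auc", n_jobs=1)
            templates[name] = est

        meta_features = np.column_stack(
            [
                cross_val_predict(
                    clone(est), X, y, cv=cv, method="predict_proba"
                )[:, 1]
                for est in templates.values()
            ]
        )
        self.meta_estimator_ = LogisticRegression(max_iter=2000).fit(meta_features, y)
        self.base_estimators_ = {
            name: clone(est).fit(X, y) for name, est in templates.items()
        }
        self.oof_meta_features_ = meta_features
        return self

    def _meta_matrix(self, X) -> np.ndarray:
        return np.column_stack(
            [est.predict_proba(X)[:, 1] for est in self.base_estimators_.values()]
        )

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.meta_estimator_.predict_proba(self._meta_matrix(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_model(name: str, random_state: int | None = None, **stacking_kwargs):
    """Estimator factory over all six model names (five bases + stacking)."""
    if name == "stacking":
        return StackingDiagnosticClassifier(random_state=random_state, **stacking_kwargs)
    return make_base_learner(name, random_state=random_state)


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerformanceRecord:
    """Cross-validated performance of one (panel, model) pair."""

    panel: str  # canonical '+'-joined marker string
    model: str
    auc: float
    sensitivity: float
    specificity: float
    n_folds: int
    seed: int
    threshold: float = 0.5

    def __post_init__(self) -> None:
        for metric in (self.auc, self.sensitivity, self.specificity):
            if not 0.0 <= metric <= 1.0:
                raise ValueError(f"metric out of [0,1]: {metric}")

    def to_dict(self) -> dict:
        return asdict(self)


def pooled_oof_scores(
    cohort: pd.DataFrame,
    panel,
    model: str = "stacking",
    k: int = 3,
    seed: int = 0,
    labels: np.ndarray | None = None,
    **model_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold predicted probabilities for every patient, pooled.

    ``k == n`` requests leave-one-out (unstratified by necessity); otherwise
    the outer split is stratified.  ``labels`` overrides the cohort's group
    labels (used for permutation nulls).
    """
    x, y = feature_matrix(cohort, panel)
    if labels is not None:
        y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    est = make_model(model, random_state=seed, **model_kwargs)
    if k == len(y):
        cv = LeaveOneOut()
    else:
        if np.bincount(y).min() < k:
            raise ValueError("each class needs at least k members")
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = cross_val_predict(est, x.to_numpy(), y, cv=cv, method="predict_proba")[:, 1]
    return scores, y


def cross_validated_evaluate(
    cohort: pd.DataFrame,
    panel,
    model: str = "stacking",
    k: int = 3,
    seed: int = 0,
    threshold: float | str = 0.5,
    **model_kwargs,
) -> PerformanceRecord:
    """Pooled out-of-fold AUC, sensitivity and specificity for one panel.

    ``threshold`` is the probability cutoff for sensitivity/specificity
    (default 0.5); pass ``"youden"`` to use the Youden-optimal cutoff on the
    pooled out-of-fold scores instead.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    scores, y = pooled_oof_scores(
        cohort, panel, model=model, k=k, seed=seed, **model_kwargs
    )
    t = youden_threshold(scores, y) if threshold == "youden" else float(threshold)
    se, sp = sens_spec(scores, y, t)
    return PerformanceRecord(
        panel=panel_str(panel),
        model=model,
        auc=compute_auc(scores, y),
        sensitivity=se,
        specificity=sp,
        n_folds=k,
        seed=seed,
        threshold=t,
    )


RECORD_COLUMNS = ["panel", "model", "cost", "auc", "sensitivity", "specificity", "k", "seed"]


def evaluate_panels(
    cohort: pd.DataFrame,
    panels,
    models=("stacking",),
    k: int = 3,
    seed: int = 0,
    prices=None,
    existing: pd.DataFrame | None = None,
    progress=None,
) -> pd.DataFrame:
    """Cross-validated records for every (panel, model) pair.

    ``existing`` lets an interrupted run resume: pairs already present are
    reused verbatim, so a resumed run's output equals an uninterrupted one.
    ``prices`` (a :class:`~mpestack.panels.PriceTable`) adds the cost column.
    """
    from .panels import DEFAULT_PRICES, panel_cost

    prices = prices if prices is not None else DEFAULT_PRICES
    done: dict[tuple[str, str], dict] = {}
    if existing is not None and len(existing):
        for _, row in existing.iterrows():
            done[(row["panel"], row["model"])] = row.to_dict()

    rows = []
    for panel in panels:
        key_panel = panel_str(panel)
        for model in models:
            if (key_panel, model) in done:
                rows.append(done[(key_panel, model)])
                continue
            rec = cross_validated_evaluate(cohort, panel, model=model, k=k, seed=seed)
            rows.append(
                {
                    "panel": rec.panel,
                    "model": rec.model,
                    "cost": panel_cost(panel, prices),
                    "auc": rec.auc,
                    "sensitivity": rec.sensitivity,
                    "specificity": rec.specificity,
                    "k": rec.n_folds,
                    "seed": rec.seed,
                }
            )
            if progress is not None:
                progress(rows[-1])
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
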