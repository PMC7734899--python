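"""The four classifier families with grid search and fold-local z-scoring.

Families
--------
EN-LR
    Elastic-net logistic regression; the grid tunes the mixing parameter
    alpha in [0, 1] step 0.1 (11 candidates).
SVM-G
    Support vector machine with Gaussian kernel; gamma and C each span
    0.1-100. The default sub-grid is the 1-2.5-5 decade ladder
    {0.1, 0.25, 0.5, 1, 2.5, 5, 10, 25, 50, 100}; the exhaustive
    0.1-step grid is available via ``full_grid=True``.
RF
    Random forest (bagged trees with random feature subsetting); tree
    count spans 50-1000 step 10.
ET-B
    Ensemble tree with bagging: bootstrap-aggregated decision trees using
    all features at every split; learning cycles (trees) span 10-200
    step 5.

Hyper-parameters are chosen by grouped 10-fold cross-validation inside the
training data, maximizing mean inner AUC; ties go to the least complex
candidate. Feature z-scoring statistics are computed on training rows only
and reapplied to test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ClassBalanceError, ConfigError, InputError, ModelStateError

FAMILIES = ("EN-LR", "SVM-G", "RF", "ET-B")

_SVM_DECADE = (0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)


def default_grid(family: str, full_grid: bool = False) -> dict:
    """Hyper-parameter grids: EN-LR alpha (0,1,0.1); SVM gamma,C (0.1,100);
    RF trees (50,1000,10); ET-B cycles (10,200,5)."""
    if family == "EN-LR":
        return {"l1_ratio": [round(a, 1) for a in np.arange(0, 1.0001, 0.1)]}
    if family == "SVM-G":
        axis = (
            [round(v, 1) for v in np.arange(0.1, 100.0001, 0.1)]
            if full_grid
            else list(_SVM_DECADE)
        )
        return {"gamma": axis, "C": axis}
    if family == "RF":
        return {"n_estimators": list(range(50, 1001, 10))}
    if family == "ET-B":
        return {"n_estimators": list(range(10, 201, 5))}
    raise ConfigError(f"unknown model family {family!r}; expected one of {FAMILIES}")


@dataclass
class ModelSpec:
    family: str
    grid: dict | None = None
    inner_folds: int = 10
    seed: int = 0
    full_grid: bool = False
    nan_policy: str = "raise"  # or "median"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}")
        if self.inner_folds < 2:
            raise ConfigError("inner_folds must be >= 2")
        if self.grid is None:
            self.grid = default_grid(self.family, self.full_grid)

    def candidates(self):
        """Grid candidates ordered least-complex first (tie-break order)."""
        keys = sorted(self.grid)
        combos = [dict(zip(keys, vals)) for vals in product(*(self.grid[k] for k in keys))]
        combos.sort(key=lambda c: _complexity_key(self.family, c))
        return combos


def _complexity_key(family: str, params: dict):
    if family == "EN-LR":
        return (-params["l1_ratio"],)  # sparser (higher l1) = simpler
    if family == "SVM-G":
        return (params["C"], params["gamma"])
    return (params["n_estimators"],)


def _make_classifier(family: str, params: dict, seed: int, probability: bool):
    if family == "EN-LR":
        return LogisticRegression(
            solver="saga", l1_ratio=params["l1_ratio"],
            C=1.0, max_iter=5000, random_state=seed,
        )
    if family == "SVM-G":
        svc = SVC(kernel="rbf", gamma=params["gamma"], C=params["C"],
                  random_state=seed)
        if probability:
            # Platt-style sigmoid calibration of the margin scores
            return CalibratedClassifierCV(svc, method="sigmoid", cv=5,
                                          ensemble=False)
        return svc
    if family == "RF":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"], random_state=seed, n_jobs=1
        )
    if family == "ET-B":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=params["n_estimators"], random_state=seed, n_jobs=1,
        )
    raise ConfigError(f"unknown model family {family!r}")


def _candidate_scores(clf, X) -> np.ndarray:
    """Rank scores for inner-CV AUC (decision_function where available)."""
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X)
    return clf.predict_proba(X)[:, 1]


@dataclass
class TrainedModel:
    family: str
    params: dict
    classifier: object
    mean: np.ndarray           # per-feature training means
    sd: np.ndarray             # per-feature training SDs
    keep_mask: np.ndarray      # False where the feature was constant (dropped)
    feature_names: list | None = None
    impute_values: np.ndarray | None = None
    inner_auc: float = float("nan")
    dropped: list = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean.size:
            raise InputError(
                f"expected {self.mean.size} features, got {X.shape[1]}"
            )
        if self.impute_values is not None:
            X = np.where(np.isnan(X), self.impute_values, X)
        Xs = (X[:, self.keep_mask] - self.mean[self.keep_mask]) / self.sd[self.keep_mask]
        return Xs


def fit(spec: ModelSpec, X, y, groups) -> TrainedModel:
    """Grid-search fit with grouped inner CV and training-only z-scoring.

    ``groups`` (recording ids) keep all epochs of a recording in one inner
    fold, preventing within-recording leakage during tuning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    if X.shape[0] != y.size or groups.size != y.size:
        raise InputError("X, y, groups must align row-wise")
    if np.unique(y).size < 2:
        raise ClassBalanceError("training set contains a single class")

    impute_values = None
    if np.isnan(X).any():
        if spec.nan_policy != "median":
            raise InputError(
                "NaN features present; set nan_policy='median' to impute"
            )
        impute_values = np.nanmedian(X, axis=0)
        impute_values = np.where(np.isnan(impute_values), 0.0, impute_values)
        X = np.where(np.isnan(X), impute_values, X)

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep_mask = sd > 0
    dropped = list(np.flatnonzero(~keep_mask))

    candidates = spec.candidates()
    if len(candidates) > 1:
        n_groups = np.unique(groups).size
        n_folds = min(spec.inner_folds, n_groups)
        if n_folds < 2:
            raise ConfigError("need >= 2 groups for inner cross-validation")
        cv = GroupKFold(n_splits=n_folds)
        fold_data = []
        for tr, va in cv.split(X, y, groups):
            if np.unique(y[tr]).size < 2 or np.unique(y[va]).size < 2:
                continue
            m, s = X[tr].mean(axis=0), X[tr].std(axis=0)
            km = s > 0
            fold_data.append(
                (
                    (X[tr][:, km] - m[km]) / s[km], y[tr],
                    (X[va][:, km] - m[km]) / s[km], y[va],
                )
            )
        if not fold_data:
            raise ClassBalanceError("no inner fold contains both classes")
        best_params, best_auc = None, -np.inf
        for params in candidates:
            aucs = []
            for Xtr, ytr, Xva, yva in fold_data:
                clf = _make_classifier(spec.family, params, spec.seed, probability=False)
                clf.fit(Xtr, ytr)
                aucs.append(roc_auc_score(yva, _candidate_scores(clf, Xva)))
            mean_auc = float(np.mean(aucs))
            if mean_auc > best_auc:  # strict: first (least complex) wins ties
                best_auc, best_params = mean_auc, params
    else:
        best_params, best_auc = candidates[0], float("nan")

    Xs = (X[:, keep_mask] - mean[keep_mask]) / sd[keep_mask]
    clf = _make_classifier(spec.family, best_params, spec.seed, probability=True)
    clf.fit(Xs, y)
    return TrainedModel(
        family=spec.family,
        params=best_params,
        classifier=clf,
        mean=mean,
        sd=sd,
        keep_mask=keep_mask,
        impute_values=impute_values,
        inner_auc=best_auc,
        dropped=dropped,
    )


def predict_probability(model: TrainedModel, X) -> np.ndarray:
    """Per-epoch probability of the sedated state, in [0, 1].

    Test features are normalized with the *training* z-score statistics.
    """
    if not isinstance(model, TrainedModel) or model.classifier is None:
        raise ModelStateError("model is not fitted")
    Xs = model.transform(np.asarray(X, dtype=float))
    proba = model.classifier.predict_proba(Xs)
    sedated_col = int(np.flatnonzero(model.classifier.classes_ == 1)[0])
    return proba[:, sedated_col]


def feature_importance(model: TrainedModel, method: str = "impurity") -> np.ndarray:
    """Per-feature importance normalized so the maximum is 1.

    Tree families use mean impurity importance across the ensemble. For the
    linear family an absolute-coefficient variant is available with
    ``method="coef"`` (reported for comparison only).
    """
    if method == "coef":
        if model.family != "EN-LR":
            raise ConfigError("coef importance only applies to EN-LR")
        raw = np.abs(np.ravel(model.classifier.coef_))
    elif model.family == "RF":
        raw = model.classifier.feature_importances_
    elif model.family == "ET-B":
        raw = np.mean(
            [t.feature_importances_ for t in model.classifier.estimators_], axis=0
        )
    else:
        raise ConfigError(
            f"feature importance unsupported for family {model.family!r}"
        )
    full = np.zeros(model.mean.size)
    full[model.keep_mask] = raw
    peak = full.max()
    return full / peak if peak > 0 else full
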