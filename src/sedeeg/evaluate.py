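"""Evaluation designs: leave-one-recording-out CV, bootstrap AUC CIs,
univariate feature AUCs, subgroup cross-matrices, and the remifentanil
stability comparison.

The outer cross-validation unit is the recording by default (a subject
option exists); the headline AUC is computed on the pooled out-of-fold
predictions because per-fold AUC is undefined for single-class recordings.
Confidence intervals resample *recordings* with replacement to respect
within-recording correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import models as m
from .errors import ClassBalanceError, ConfigError
from .features import FEATURE_NAMES, feature_matrix

POSITIVE_LABEL = "sedated"


@dataclass
class EvaluationResult:
    predictions: pd.DataFrame          # provenance + fold + probability
    auc: float
    auc_ci: tuple
    sensitivity: float
    specificity: float
    f1: float
    importances: np.ndarray | None = None   # folds x 44, each fold max-normalized
    feature_names: list = field(default_factory=lambda: list(FEATURE_NAMES))
    subgroup_matrix: dict | None = None
    chosen_params: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc_point(labels, scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 0.5)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ClassBalanceError("AUC undefined for a single class")
    return float(roc_auc_score(labels, scores))


def auc_with_ci(labels, scores, groups=None, n_boot=1000, seed=0):
    """AUC with a percentile bootstrap 95% CI.

    Resampling is at the recording level when ``groups`` is given (each
    draw resamples recordings with replacement and pools their epochs),
    otherwise at the epoch level. Bootstrap draws with a single class are
    discarded.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    point = auc_point(labels, scores)
    rng = np.random.default_rng(seed)
    boots = []
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        index = {g: np.flatnonzero(groups == g) for g in uniq}
        for _ in range(n_boot):
            pick = rng.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([index[g] for g in pick])
            if np.unique(labels[idx]).size < 2:
                continue
            boots.append(roc_auc_score(labels[idx], scores[idx]))
    else:
        n = labels.size
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if np.unique(labels[idx]).size < 2:
                continue
            boots.append(roc_auc_score(labels[idx], scores[idx]))
    if not boots:
        return point, np.nan, np.nan
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, float(lo), float(hi)


def classification_metrics(labels, scores, threshold=0.5):
    """Sensitivity, specificity, F1 with sedated as the positive class."""
    labels = np.asarray(labels, dtype=int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
    return sens, spec, f1


# ---------------------------------------------------------------------------
# leave-one-recording-out cross-validation
# ---------------------------------------------------------------------------

def loocv(dataset: pd.DataFrame, spec: m.ModelSpec, cv_unit: str = "recording",
          n_boot: int = 1000, seed: int = 0) -> EvaluationResult:
    """Leave-one-recording-out (or -subject-out) evaluation.

    One outer fold per unit: the model (with its inner grid search) is
    fitted on the remaining units and predicts every epoch of the left-out
    unit. Out-of-fold probabilities are pooled into one AUC; a left-out
    unit whose epochs are all one class is still predicted.
    """
    if cv_unit == "recording":
        unit_col = "recording_id"
    elif cv_unit == "subject":
        unit_col = "subject_id"
    else:
        raise ConfigError(f"cv_unit must be 'recording' or 'subject', got {cv_unit!r}")
    if unit_col not in dataset.columns:
        raise ConfigError(f"dataset lacks a {unit_col!r} column")

    X, y, _ = feature_matrix(dataset)
    units = dataset[unit_col].to_numpy()
    uniq = list(pd.unique(units))
    if len(uniq) < 3:
        raise ConfigError("leave-one-out evaluation needs >= 3 units")

    prob = np.full(y.size, np.nan)
    fold_of = np.full(y.size, -1)
    importances, chosen = [], []
    tree_family = spec.family in ("RF", "ET-B")
    for fold, unit in enumerate(uniq):
        test = units == unit
        train = ~test
        model = m.fit(spec, X[train], y[train], dataset["recording_id"].to_numpy()[train])
        prob[test] = m.predict_probability(model, X[test])
        fold_of[test] = fold
        chosen.append(model.params)
        if tree_family:
            importances.append(m.feature_importance(model))

    predictions = dataset[
        [c for c in ("recording_id", "subject_id", "segment_index", "epoch_index", "label")
         if c in dataset.columns]
    ].copy()
    predictions["fold"] = fold_of
    predictions["probability"] = prob

    auc, lo, hi = auc_with_ci(y, prob, groups=units, n_boot=n_boot, seed=seed)
    sens, spc, f1 = classification_metrics(y, prob)
    return EvaluationResult(
        predictions=predictions,
        auc=auc,
        auc_ci=(lo, hi),
        sensitivity=sens,
        specificity=spc,
        f1=f1,
        importances=np.vstack(importances) if importances else None,
        chosen_params=chosen,
    )


# ---------------------------------------------------------------------------
# univariate feature screening
# ---------------------------------------------------------------------------

def univariate_feature_auc(dataset: pd.DataFrame, n_boot: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Direction-agnostic AUC of each feature used directly as the score.

    Orientation is corrected as max(AUC, 1-AUC); constant features report
    0.5 and are flagged.
    """
    X, y, groups = feature_matrix(dataset)
    rows = []
    for j, name in enumerate(FEATURE_NAMES):
        x = X[:, j]
        ok = ~np.isnan(x)
        if np.ptp(x[ok]) == 0 or np.unique(y[ok]).size < 2:
            rows.append({"feature": name, "auc": 0.5, "ci_lo": np.nan,
                         "ci_hi": np.nan, "constant": True})
            continue
        auc, lo, hi = auc_with_ci(y[ok], x[ok], groups=groups[ok],
                                  n_boot=n_boot, seed=seed + j)
        if auc < 0.5:
            auc, lo, hi = 1 - auc, 1 - hi, 1 - lo
        rows.append({"feature": name, "auc": auc, "ci_lo": lo, "ci_hi": hi,
                     "constant": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroup robustness designs
# ---------------------------------------------------------------------------

DEFAULT_AGE_BOUNDS = ((18.0, 35.0), (35.0, 50.0), (50.0, 70.0))


@dataclass(frozen=True)
class GroupSplit:
    criterion: str  # age | sex | drug | remifentanil
    age_bounds: tuple = DEFAULT_AGE_BOUNDS

    def assign(self, dataset: pd.DataFrame) -> np.ndarray:
        if self.criterion == "age":
            ages = dataset["age_years"].to_numpy(dtype=float)
            out = np.full(ages.size, -1, dtype=object)
            for i, (lo, hi) in enumerate(self.age_bounds, start=1):
                mask = (ages >= lo) & (ages < hi) if i < len(self.age_bounds) else (
                    (ages >= lo) & (ages <= hi)
                )
                out[mask] = f"group{i}"
            return out
        if self.criterion in ("sex", "drug", "remifentanil"):
            return dataset[self.criterion].astype(str).to_numpy()
        raise ConfigError(f"unknown split criterion {self.criterion!r}")

    def expected_groups(self, dataset: pd.DataFrame) -> list:
        """The full partition the criterion defines (all must be nonempty)."""
        if self.criterion == "age":
            return [f"group{i}" for i in range(1, len(self.age_bounds) + 1)]
        if self.criterion == "sex":
            return ["female", "male"]
        if self.criterion == "remifentanil":
            return ["False", "True"]
        return sorted(set(dataset[self.criterion].astype(str)))


def cross_group_matrix(dataset: pd.DataFrame, split: GroupSplit, spec: m.ModelSpec,
                       n_boot: int = 1000, seed: int = 0) -> dict:
    """Within/cross-group AUC matrix.

    Diagonal cells are within-group leave-one-recording-out AUCs;
    off-diagonal cells train on all of group A and test on every epoch of
    group B. Each cell carries a bootstrap CI.
    """
    labels = split.assign(dataset)
    if any(l == -1 for l in labels):
        raise ConfigError("some rows fall outside the group bounds")
    names = split.expected_groups(dataset)
    for g in names:
        if not np.any(labels == g):
            raise ConfigError(f"group {g} is empty")
    matrix = {}
    for a in names:
        da = dataset[labels == a]
        if not len(da):
            raise ConfigError(f"group {a} is empty")
        res = loocv(da, spec, n_boot=n_boot, seed=seed)
        matrix[(a, a)] = (res.auc, *res.auc_ci)
        Xa, ya, ga = feature_matrix(da)
        model = m.fit(spec, Xa, ya, ga)
        for b in names:
            if b == a:
                continue
            db = dataset[labels == b]
            if not len(db):
                raise ConfigError(f"group {b} is empty")
            Xb, yb, gb = feature_matrix(db)
            prob = m.predict_probability(model, Xb)
            matrix[(a, b)] = auc_with_ci(yb, prob, groups=gb, n_boot=n_boot, seed=seed)
    return matrix


def _per_recording_aucs(dataset, result: EvaluationResult) -> list:
    """AUC computed within each recording whose epochs span both classes."""
    y = (dataset["label"] == POSITIVE_LABEL).to_numpy(dtype=int)
    scores = result.predictions["probability"].to_numpy()
    groups = dataset["recording_id"].to_numpy()
    out = []
    for g in np.unique(groups):
        idx = groups == g
        if np.unique(y[idx]).size == 2:
            out.append(roc_auc_score(y[idx], scores[idx]))
    return out


def stability_experiment(dataset_without: pd.DataFrame, dataset_with: pd.DataFrame,
                         specs, n_boot: int = 1000, seed: int = 0,
                         anova: bool = True) -> pd.DataFrame:
    """Per-model LOOCV AUC with vs. without the remifentanil arm.

    Reports the AUC change and a two-sided recording-level bootstrap
    p-value of the difference computed from the pooled out-of-fold
    predictions (no refitting inside the bootstrap). With ``anova=True``
    a one-way ANOVA p-value across the models' per-recording AUCs is
    appended per condition as a standard-test column.
    """
    missing = set(FEATURE_NAMES) - set(dataset_without.columns) | (
        set(FEATURE_NAMES) - set(dataset_with.columns)
    )
    if missing:
        raise ConfigError(f"feature schema mismatch; missing columns {sorted(missing)}")
    identical = dataset_without.equals(dataset_with)
    rows, per_rec = [], []
    rng = np.random.default_rng(seed)
    for spec in specs:
        res_wo = loocv(dataset_without, spec, n_boot=n_boot, seed=seed)
        res_wi = (
            res_wo if identical else loocv(dataset_with, spec, n_boot=n_boot, seed=seed)
        )
        delta = res_wi.auc - res_wo.auc
        if identical:
            pval = 1.0
        else:
            deltas = []
            for _ in range(n_boot):
                b_wo = _bootstrap_auc_once(dataset_without, res_wo, rng)
                b_wi = _bootstrap_auc_once(dataset_with, res_wi, rng)
                if b_wo is not None and b_wi is not None:
                    deltas.append(b_wi - b_wo)
            deltas = np.asarray(deltas)
            if deltas.size:
                frac_le = np.mean(deltas <= 0)
                frac_ge = np.mean(deltas >= 0)
                pval = float(min(1.0, 2 * min(frac_le, frac_ge)))
            else:
                pval = np.nan
        rows.append(
            {
                "model": spec.family,
                "auc_without": res_wo.auc,
                "ci_without": res_wo.auc_ci,
                "auc_with": res_wi.auc,
                "ci_with": res_wi.auc_ci,
                "delta_auc": delta,
                "p_bootstrap": pval,
            }
        )
        per_rec.append(
            (_per_recording_aucs(dataset_without, res_wo),
             _per_recording_aucs(dataset_with, res_wi))
        )
    out = pd.DataFrame(rows)
    if anova and len(specs) >= 2:
        from scipy.stats import f_oneway

        wo_groups = [g[0] for g in per_rec if len(g[0]) >= 2]
        wi_groups = [g[1] for g in per_rec if len(g[1]) >= 2]
        out["p_anova_without"] = (
            f_oneway(*wo_groups).pvalue if len(wo_groups) >= 2 else np.nan
        )
        out["p_anova_with"] = (
            f_oneway(*wi_groups).pvalue if len(wi_groups) >= 2 else np.nan
        )
    return out


def _bootstrap_auc_once(dataset, result: EvaluationResult, rng):
    y = (dataset["label"] == POSITIVE_LABEL).to_numpy(dtype=int)
    scores = result.predictions["probability"].to_numpy()
    groups = dataset["recording_id"].to_numpy()
    uniq = np.unique(groups)
    pick = rng.choice(uniq, size=uniq.size, replace=True)
    idx = np.concatenate([np.flatnonzero(groups == g) for g in pick])
    if np.unique(y[idx]).size < 2:
        return None
    return roc_auc_score(y[idx], scores[idx])


def importance_summary(per_fold_importances, threshold: float = 0.3,
                       feature_names=FEATURE_NAMES) -> list:
    """Feature names whose mean fold-normalized weight is >= threshold,
    in canonical order."""
    imp = np.atleast_2d(np.asarray(per_fold_importances, dtype=float))
    means = imp.mean(axis=0)
    return [name for name, v in zip(feature_names, means) if v >= threshold]
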