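"""Immunotherapy-response classification from estimated cell abundances.

Procedure: balance the training classes by undersampling the majority
class, prune features by sequential backward selection against stratified
fivefold cross-validated AUC, fit an RBF-kernel SVM on the selected
features, and report ranking AUC (from decision-function scores, which
need no probability calibration) on held-out cohorts. Feature selection
and fitting see only the training cohort; holdouts are scored once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import ValidationError

__all__ = [
    "ResponseCohort",
    "ModelReport",
    "undersample",
    "cv_auc",
    "backward_select",
    "train_and_evaluate",
    "save_model",
    "load_model",
    "predict_scores",
]

logger = logging.getLogger(__name__)

N_FOLDS = 5
SVM_PARAMS = {"kernel": "rbf", "C": 1.0, "gamma": "scale"}


@dataclass
class ResponseCohort:
    """Samples x cell-type abundance features with binary response labels.

    Labels: 1 = responder (complete/partial response), 0 = non-responder
    (stable/progressive disease).
    """

    features: pd.DataFrame
    labels: pd.Series
    name: str = ""

    def __post_init__(self):
        self.labels = self.labels.reindex(self.features.index)
        if self.labels.isna().any():
            raise ValidationError("every sample needs a label")
        values = set(self.labels.unique().tolist())
        if not values <= {0, 1}:
            raise ValidationError("labels must be binary (0/1)")
        if not np.isfinite(self.features.to_numpy(dtype=float)).all():
            raise ValidationError("features must be finite")


@dataclass
class ModelReport:
    selected_features: List[str]
    cv_auc: float
    test_auc: Dict[str, Optional[float]]
    seed: int
    hyperparameters: Dict = field(default_factory=dict)
    model: Optional[SVC] = None
    training: Optional[ResponseCohort] = None


def undersample(
    cohort: ResponseCohort, seed: int, n_per_class: Optional[int] = None
) -> ResponseCohort:
    """Balance classes by subsampling (majority class down to the minority).

    With ``n_per_class`` given, both classes are subsampled to that size
    (e.g. a 27/64 cohort reduced to a 19/19 training split, leaving the
    remainder for testing).
    """
    rng = np.random.default_rng(seed)
    idx_pos = cohort.labels.index[cohort.labels == 1]
    idx_neg = cohort.labels.index[cohort.labels == 0]
    if len(idx_pos) == 0 or len(idx_neg) == 0:
        raise ValidationError("both classes must be present")
    target = n_per_class if n_per_class is not None else min(len(idx_pos), len(idx_neg))
    if target > min(len(idx_pos), len(idx_neg)):
        raise ValidationError("n_per_class exceeds the minority class size")
    if n_per_class is None and len(idx_pos) == len(idx_neg):
        return cohort  # already balanced
    keep = []
    for idx in (idx_pos, idx_neg):
        if len(idx) == target:
            keep.extend(idx)
        else:
            keep.extend(rng.choice(np.asarray(idx, dtype=object), size=target, replace=False))
    keep = [k for k in cohort.features.index if k in set(keep)]  # stable order
    return ResponseCohort(
        features=cohort.features.loc[keep],
        labels=cohort.labels.loc[keep],
        name=cohort.name,
    )


def _fit_svm(x: np.ndarray, y: np.ndarray) -> SVC:
    model = SVC(**SVM_PARAMS)
    model.fit(x, y)
    return model


def cv_auc(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int,
    n_folds: int = N_FOLDS,
    _depth: int = 0,
) -> float:
    """Mean AUC over stratified k-fold cross-validation.

    A degenerate fold (single-class training or test split) triggers one
    refold with seed+1; the event is logged.
    """
    x = features.to_numpy(dtype=float)
    y = labels.to_numpy(dtype=int)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in splitter.split(x, y):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            if _depth >= 3:
                raise ValidationError("labels too degenerate for cross-validation")
            logger.warning("degenerate CV fold; refolding with seed %d", seed + 1)
            return cv_auc(features, labels, seed + 1, n_folds, _depth + 1)
        model = _fit_svm(x[train_idx], y[train_idx])
        scores = model.decision_function(x[test_idx])
        aucs.append(roc_auc_score(y[test_idx], scores))
    return float(np.mean(aucs))


def backward_select(
    cohort: ResponseCohort, seed: int, n_folds: int = N_FOLDS
) -> List[str]:
    """Sequential backward feature elimination against CV AUC.

    Repeatedly drop the feature whose removal yields the highest CV AUC,
    as long as that AUC is at least the current one (ties favour the
    smaller feature set, broken by feature order); stop when every removal
    strictly hurts, or when a single feature remains.
    """
    features = list(cohort.features.columns)
    if len(features) < 2:
        raise ValidationError("backward selection needs at least 2 features")
    current = cv_auc(cohort.features[features], cohort.labels, seed, n_folds)
    while len(features) > 1:
        best_auc, best_feature = -np.inf, None
        for f in features:
            reduced = [g for g in features if g != f]
            auc = cv_auc(cohort.features[reduced], cohort.labels, seed, n_folds)
            if auc > best_auc:
                best_auc, best_feature = auc, f
        if best_auc >= current:
            features.remove(best_feature)
            current = best_auc
        else:
            break
    return features


def train_and_evaluate(
    train: ResponseCohort,
    holdouts: Sequence[ResponseCohort],
    seed: int,
    n_per_class: Optional[int] = None,
    select: bool = True,
) -> ModelReport:
    """Undersample, select features, fit the SVM, score each holdout.

    Holdout cohorts never influence selection or fitting. A holdout with a
    single class has an undefined AUC and is reported as None.
    """
    balanced = undersample(train, seed, n_per_class=n_per_class)
    if select:
        selected = backward_select(balanced, seed)
    else:
        selected = list(balanced.features.columns)
    final_cv = cv_auc(balanced.features[selected], balanced.labels, seed)
    model = _fit_svm(
        balanced.features[selected].to_numpy(dtype=float),
        balanced.labels.to_numpy(dtype=int),
    )
    test_auc: Dict[str, Optional[float]] = {}
    for i, cohort in enumerate(holdouts):
        key = cohort.name or f"holdout_{i + 1}"
        y = cohort.labels.to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            test_auc[key] = None
            continue
        scores = model.decision_function(cohort.features[selected].to_numpy(dtype=float))
        test_auc[key] = float(roc_auc_score(y, scores))
    return ModelReport(
        selected_features=selected,
        cv_auc=final_cv,
        test_auc=test_auc,
        seed=seed,
        hyperparameters=dict(SVM_PARAMS),
        model=model,
        training=balanced,
    )


def save_model(report: ModelReport, path) -> None:
    """Serialise a trained model portably as JSON.

    The file stores the seed, hyperparameters, selected features and the
    balanced training data; :func:`load_model` refits the (deterministic)
    SVM from those, so no binary pickle is involved.
    """
    if report.training is None:
        raise ValidationError("report carries no training data to serialise")
    payload = {
        "format": "immusig-response-model/1",
        "seed": report.seed,
        "hyperparameters": report.hyperparameters,
        "selected_features": report.selected_features,
        "cv_auc": report.cv_auc,
        "training_features": report.training.features[report.selected_features]
        .rename_axis("index")
        .reset_index()
        .to_dict(orient="list"),
        "training_labels": report.training.labels.astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> ModelReport:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "immusig-response-model/1":
        raise ValidationError("unrecognised model file format")
    tf = pd.DataFrame(payload["training_features"]).set_index("index")
    labels = pd.Series(payload["training_labels"], index=tf.index)
    cohort = ResponseCohort(features=tf, labels=labels, name="training")
    model = _fit_svm(tf.to_numpy(dtype=float), labels.to_numpy(dtype=int))
    return ModelReport(
        selected_features=payload["selected_features"],
        cv_auc=payload["cv_auc"],
        test_auc={},
        seed=payload["seed"],
        hyperparameters=payload["hyperparameters"],
        model=model,
        training=cohort,
    )


def predict_scores(report: ModelReport, features: pd.DataFrame) -> pd.Series:
    """Decision-function scores (higher = more responder-like)."""
    if report.model is None:
        raise ValidationError("report carries no fitted model")
    x = features[report.selected_features].to_numpy(dtype=float)
    return pd.Series(report.model.decision_function(x), index=features.index)
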