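"""Class-weight-balanced, L2-penalized logistic regression with repeated
stratified cross-validation, external scoring, and prefix-restricted refits.

The classifier minimizes

    (1/2)||w||^2 + C * sum_i omega_i * logloss_i

with C = 1 by default (penalty weighed equally with the error term) and
balanced class weights omega_i = n / (2 * n_class(i)), so that a roughly 2:1
noncancer:cancer imbalance does not bias the fit.  The evaluation protocol
is 5-fold stratified cross-validation repeated 10 times, recording each
sample's mean held-out score across repeats; a full-cohort refit is then
scored on an external validation cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .synthetic_cohort import FeatureTable

CONTEXTS = ("screening", "diagnostic")
#: Conditions kept per context; cancer is always the positive class.
CONTEXT_CONDITIONS = {
    "screening": ("healthy", "cancer"),
    "diagnostic": ("benign", "cancer"),
}
POSITIVE_CONDITION = "cancer"


@dataclass(frozen=True)
class ModelConfig:
    """Training and cross-validation configuration."""

    context: str = "screening"
    features: Tuple[str, ...] = ()
    C: float = 1.0
    class_weight: str | None = "balanced"
    cv_folds: int = 5
    cv_repeats: int = 10
    standardize: bool = False
    tol: float = 1e-10
    max_iter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be positive")

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


@dataclass
class FittedLinearModel:
    """Binary linear-logistic classifier: score(x) = logistic(w.x + b)."""

    coefficients: np.ndarray
    intercept: float
    feature_names: Tuple[str, ...]
    training_sds: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("one coefficient per feature required")
        if self.training_sds is None:
            self.training_sds = np.ones_like(self.coefficients)
        self.training_sds = np.asarray(self.training_sds, dtype=float).ravel()

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(X))

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "training_sds": self.training_sds.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedLinearModel":
        d = json.loads(text)
        return cls(
            np.array(d["coefficients"]),
            float(d["intercept"]),
            tuple(d["feature_names"]),
            np.array(d["training_sds"]),
        )


@dataclass
class CVScores:
    """Per-sample mean held-out scores across all cross-validation repeats."""

    sample_ids: Tuple[str, ...]
    mean_scores: np.ndarray
    labels: np.ndarray
    fold_assignments: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": self.labels.astype(int),
                "mean_score": self.mean_scores,
            }
        )


def select_context(
    table: FeatureTable, metadata: pd.DataFrame, context: str
) -> Tuple[FeatureTable, np.ndarray]:
    """Restrict to the context's two conditions; labels are 1 for cancer.

    ``screening`` keeps healthy + cancer; ``diagnostic`` keeps benign +
    cancer.  Raises if either class is absent.
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")
    negative, positive = CONTEXT_CONDITIONS[context]
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    conditions = meta.loc[table.sample_ids, "condition"]
    keep = conditions.isin([negative, positive])
    kept_conditions = conditions[keep]
    for cls in (negative, positive):
        if not (kept_conditions == cls).any():
            raise ValueError(f"no {cls!r} samples available for the {context} context")
    subset = table.subset_samples(list(kept_conditions.index))
    labels = (kept_conditions == POSITIVE_CONDITION).to_numpy()
    return subset, labels


def _estimator(config: ModelConfig, seed: int | None = None) -> LogisticRegression:
    return LogisticRegression(
        C=config.C,
        class_weight=config.class_weight,
        solver="lbfgs",
        tol=config.tol,
        max_iter=config.max_iter,
        random_state=0 if seed is None else seed,
    )


def fit(features: pd.DataFrame, labels: np.ndarray, config: ModelConfig) -> FittedLinearModel:
    """Fit the penalized, class-weighted logistic regression.

    Training-set per-feature sample SDs are retained on the model for later
    scaled-coefficient / importance calculations.  The problem is convex, so
    the fit is deterministic given the inputs and tolerance.
    """
    labels = np.asarray(labels).astype(bool)
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in features")
    for cls in (False, True):
        if (labels == cls).sum() < 2:
            raise ValueError("need at least 2 samples in each class")
    sds = features.std(axis=0, ddof=1).to_numpy()
    if config.standardize:
        safe = np.where(sds > 0, sds, 1.0)
        X = (X - X.mean(axis=0)) / safe
    est = _estimator(config)
    est.fit(X, labels.astype(int))
    if est.n_iter_[0] >= config.max_iter:
        raise RuntimeError(
            f"logistic regression did not converge in {config.max_iter} iterations "
            f"(tol={config.tol}); n={len(labels)}, p={X.shape[1]}"
        )
    coef = est.coef_.ravel().copy()
    intercept = float(est.intercept_[0])
    if config.standardize:
        # Fold the standardization back into raw-feature coefficients.
        means = features.to_numpy(dtype=float).mean(axis=0)
        coef = coef / np.where(sds > 0, sds, 1.0)
        intercept -= float(coef @ means)
    return FittedLinearModel(coef, intercept, tuple(features.columns), sds)


def repeated_stratified_cv(
    features: pd.DataFrame, labels: np.ndarray, config: ModelConfig
) -> CVScores:
    """Repeated stratified k-fold CV returning per-sample mean held-out scores.

    Repeat ``r`` shuffles folds with seed ``config.seed + r`` so repeats
    differ but runs are reproducible.  Every sample is scored exactly once
    per repeat, always by a model trained without its fold.
    """
    labels = np.asarray(labels).astype(bool)
    n = len(labels)
    for cls in (False, True):
        if (labels == cls).sum() < config.cv_folds:
            raise ValueError(
                f"class with {(labels == cls).sum()} members is smaller than k={config.cv_folds}"
            )
    scores = np.zeros(n)
    fold_records = []
    y = labels.astype(int)
    for r in range(config.cv_repeats):
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed + r)
        for fold_idx, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
            model = fit(features.iloc[train_idx], labels[train_idx], config)
            scores[test_idx] += model.predict_proba(features.iloc[test_idx].to_numpy())
            for i in test_idx:
                fold_records.append((r, fold_idx, features.index[i]))
    scores /= config.cv_repeats
    folds = pd.DataFrame(fold_records, columns=["repeat", "fold", "sample_id"])
    return CVScores(tuple(features.index), scores, labels, folds)


def decision_boundary(model: FittedLinearModel) -> Tuple[float, float]:
    """Slope and intercept of the decision line w1*x + w2*y + b = 0.

    Defined only for two-feature models with a nonzero second coefficient:
    slope = -w1/w2, intercept = -b/w2.
    """
    if len(model.coefficients) != 2:
        raise ValueError(f"decision boundary requires exactly 2 features, got {len(model.coefficients)}")
    w1, w2 = model.coefficients
    if w2 == 0:
        raise ValueError("second coefficient is zero; boundary is vertical")
    return -w1 / w2, -model.intercept / w2


def train_context_model(
    table: FeatureTable, metadata: pd.DataFrame, config: ModelConfig
) -> Tuple[FittedLinearModel, CVScores]:
    """CV then full refit on one context's discovery-style data."""
    subset, labels = select_context(table, metadata, config.context)
    feats = subset.values[list(config.features)] if config.features else subset.values
    cv = repeated_stratified_cv(feats, labels, config)
    model = fit(feats, labels, config)
    return model, cv


def restrict_and_refit(
    table: FeatureTable,
    metadata: pd.DataFrame,
    excluded_prefix: str,
    config: ModelConfig,
) -> Tuple[FittedLinearModel, CVScores]:
    """Drop every sample with ``excluded_prefix``, then run the usual protocol.

    Emulates retraining after removing a batch-confounded sample subset;
    everything downstream of the removal is identical to the unrestricted
    protocol.
    """
    meta = metadata.copy()
    keep_ids = meta.loc[meta["prefix"] != excluded_prefix, "sample_id"]
    kept = table.subset_samples([s for s in table.sample_ids if s in set(keep_ids)])
    try:
        return train_context_model(kept, meta, config)
    except ValueError as err:
        raise ValueError(f"after excluding prefix {excluded_prefix!r}: {err}") from err


def score_external(model: FittedLinearModel, features: pd.DataFrame) -> pd.Series:
    """Score held-out samples with a fitted model (pure function).

    Columns are aligned to the model's feature order; a missing column is an
    error.
    """
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    X = features[list(model.feature_names)].to_numpy(dtype=float)
    return pd.Series(model.predict_proba(X), index=features.index, name="score")
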