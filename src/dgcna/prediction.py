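"""Expression-based condition prediction with boosted trees.

A gradient-boosted decision-tree classifier (binary logistic objective) is
evaluated per feature gene set by repeated stratified k-fold cross-validation
(default ten rounds of 5-fold), reporting the mean held-out AUC and the mean
misclassification rate at probability 0.5 — the two headline metrics for
expression-based case/control prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .containers import ExpressionMatrix, ParameterError


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(random positive outscores a random negative).

    Ties count one half.  Labels must contain both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class FeatureSetSpec:
    name: str
    genes: list[str]


@dataclass
class PredictionReport:
    feature_set: str
    folds_table: pd.DataFrame  # columns: round, fold, auc, error
    rounds: int
    folds: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(self.folds_table["auc"].mean())

    @property
    def sd_auc(self) -> float:
        return float(self.folds_table["auc"].std(ddof=1))

    @property
    def mean_error(self) -> float:
        return float(self.folds_table["error"].mean())

    @property
    def sd_error(self) -> float:
        return float(self.folds_table["error"].std(ddof=1))

    def summary(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_error": self.mean_error,
            "sd_error": self.sd_error,
            "rounds": self.rounds,
            "folds": self.folds,
        }


def make_booster(seed: int, n_estimators: int = 100, max_depth: int = 4,
                 learning_rate: float = 0.1) -> XGBClassifier:
    return XGBClassifier(
        objective="binary:logistic",
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        verbosity=0,
    )


def cross_validated_boosting(
    expr: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series | np.ndarray,
    features: FeatureSetSpec,
    rounds: int = 10,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int = 4,
    learning_rate: float = 0.1,
) -> PredictionReport:
    """Repeated stratified k-fold CV of a boosted-tree classifier.

    Each round draws a fresh seeded stratified partition; per fold the model
    is fit on the training folds and scored on the held-out fold (AUC and
    misclassification at 0.5).  Expression is genes x samples; ``features``
    selects the gene rows used as predictors.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if not features.genes:
        raise ParameterError(f"feature set {features.name!r} is empty")
    missing = [g for g in features.genes if g not in values.index]
    if missing:
        raise ParameterError(
            f"feature genes missing from the expression matrix: {missing[:10]}"
        )
    X = values.loc[features.genes].T.to_numpy(dtype=float)  # samples x genes
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if len(classes) != 2:
        raise ParameterError(f"need exactly 2 classes, got {list(classes)}")
    y = (y_raw == classes[1]).astype(int)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ParameterError(
            f"need >= {folds} samples per class for {folds}-fold stratified CV"
        )
    rows = []
    for rnd in range(rounds):
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=(seed * 1009 + rnd) % (2**31)
        )
        for fold, (train, test) in enumerate(splitter.split(X, y)):
            model = make_booster(
                seed=(seed * 131 + rnd) % (2**31),
                n_estimators=n_estimators,
                max_depth=max_depth,
                learning_rate=learning_rate,
            )
            model.fit(X[train], y[train])
            prob = model.predict_proba(X[test])[:, 1]
            fold_auc = auc(prob, y[test])
            fold_err = float(np.mean((prob >= 0.5).astype(int) != y[test]))
            rows.append({"round": rnd, "fold": fold, "auc": fold_auc, "error": fold_err})
    return PredictionReport(
        feature_set=features.name,
        folds_table=pd.DataFrame(rows),
        rounds=rounds,
        folds=folds,
        seed=seed,
    )


def evaluate_feature_sets(
    expr: ExpressionMatrix | pd.DataFrame,
    labels,
    feature_sets: list[FeatureSetSpec],
    **cv_params,
) -> pd.DataFrame:
    """CV report summary per feature set, one row each."""
    summaries = [
        cross_validated_boosting(expr, labels, spec, **cv_params).summary()
        for spec in feature_sets
    ]
    return pd.DataFrame(summaries)
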