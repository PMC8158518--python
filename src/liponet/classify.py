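"""Random-Forest classification with resampling and permutation significance.

The two study groups are compared with a Random Forest under a stratified
resampling scheme: per iteration, an equal-size training sample of
``floor(train_fraction * min(n1, n2))`` subjects per class is drawn without
replacement, the forest is scored on the held-out remainder, and accuracy,
sensitivity, specificity and AUC are averaged over the iterations with
percentile 95% confidence intervals.

Significance of each quality metric uses a label-permutation null with the
p-value computed as

    p = (1 + #{null >= observed}) / K

for K permutations — so the smallest attainable p is 1/K (0.001 at the
default K = 1000) and the largest is (1 + K)/K.  Variable importance is the
mean decrease in Gini impurity, with per-variable permutation p-values from
the same kind of null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score


def eq_permutation_pvalue(n_exceed: int, K: int) -> float:
    """Permutation p-value (1 + #exceedances) / K, as printed on the report.

    ``n_exceed`` counts null statistics at least as extreme as the observed
    one.  By construction the value lies in [1/K, (1 + K)/K].
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_exceed < 0 or n_exceed > K:
        raise ValueError("exceedance count must lie in [0, K]")
    return (1.0 + n_exceed) / K


METRICS = ("accuracy", "sensitivity", "specificity", "auc")


@dataclass
class RfQualityReport:
    """Mean, 95% CI and permutation p per quality metric; one row each."""

    table: pd.DataFrame          # index METRICS; columns mean, ci_lower, ci_upper, p_value
    per_iteration: pd.DataFrame  # iteration x metric raw values


@dataclass
class RfSettings:
    """Forest and resampling configuration."""

    n_estimators: int = 500
    train_fraction: float = 0.85
    n_resamples: int = 100
    n_permutations: int = 1000
    min_class_size: int = 10
    max_features: str | float = "sqrt"


def stratified_resample_indices(
    y, train_fraction: float = 0.85, n_iter: int = 100,
    seed: int | None = None, min_class_size: int = 10,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Equal-size per-class train/test splits, repeated ``n_iter`` times.

    The per-class training size is ``floor(train_fraction * min(n1, n2))``,
    drawn without replacement within each class; every sample not drawn for
    training goes to the test set.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    rng = np.random.default_rng(seed)
    n_min = min(int((y == c).sum()) for c in classes)
    if n_min < min_class_size:
        raise ValueError(f"smallest class has {n_min} samples; need >= {min_class_size}")
    n_train = int(np.floor(train_fraction * n_min))
    splits = []
    for _ in range(n_iter):
        train = np.concatenate(
            [rng.choice(np.flatnonzero(y == c), size=n_train, replace=False)
             for c in classes]
        )
        mask = np.ones(y.size, dtype=bool)
        mask[train] = False
        splits.append((np.sort(train), np.flatnonzero(mask)))
    return splits


def _metrics_from_predictions(y_true, y_pred, scores, positive) -> dict[str, float]:
    pos = y_true == positive
    tp = np.sum(y_pred[pos] == positive)
    tn = np.sum(y_pred[~pos] != positive)
    return {
        "accuracy": float(np.mean(y_pred == y_true)),
        "sensitivity": float(tp / max(pos.sum(), 1)),
        "specificity": float(tn / max((~pos).sum(), 1)),
        "auc": float(roc_auc_score(pos.astype(int), scores)),
    }


def fit_and_score(
    X, y, indices, settings: RfSettings | None = None, seed: int | None = None,
) -> pd.DataFrame:
    """Train/score the forest on each split; returns iteration x metric table.

    The positive class (for sensitivity/AUC) is the lexicographically last
    label.  Iterations whose training split collapses to one class are
    skipped with a warning.
    """
    settings = settings or RfSettings()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    positive = np.unique(y)[-1]
    rng = np.random.default_rng(seed)
    rows = []
    for train, test in indices:
        if np.unique(y[train]).size < 2:
            warnings.warn("single-class training split skipped", stacklevel=2)
            continue
        forest = RandomForestClassifier(
            n_estimators=settings.n_estimators,
            max_features=settings.max_features,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(X[train], y[train])
        pos_col = list(forest.classes_).index(positive)
        scores = forest.predict_proba(X[test])[:, pos_col]
        rows.append(
            _metrics_from_predictions(y[test], forest.predict(X[test]), scores, positive)
        )
    return pd.DataFrame(rows)


def _mean_metrics(per_iter: pd.DataFrame) -> pd.Series:
    return per_iter.mean(axis=0)


def rf_quality_report(
    X, y, settings: RfSettings | None = None, seed: int | None = None,
) -> RfQualityReport:
    """Full quality report: resampled metrics plus permutation p-values.

    Each of the ``n_permutations`` null replicates re-runs the complete
    resampled fit on label-permuted data and records the mean of every
    metric; p-values follow the (1 + #) / K formula.
    """
    settings = settings or RfSettings()
    y = np.asarray(y)
    root = np.random.default_rng(seed)
    s_split, s_fit, s_perm = root.spawn(3)

    indices = stratified_resample_indices(
        y, settings.train_fraction, settings.n_resamples,
        seed=s_split, min_class_size=settings.min_class_size,
    )
    per_iter = fit_and_score(X, y, indices, settings, seed=s_fit)
    observed = _mean_metrics(per_iter)
    ci = per_iter.quantile([0.025, 0.975])

    exceed = {m: 0 for m in METRICS}
    for _ in range(settings.n_permutations):
        y_perm = s_perm.permutation(y)
        idx_p = stratified_resample_indices(
            y_perm, settings.train_fraction, settings.n_resamples,
            seed=s_perm, min_class_size=settings.min_class_size,
        )
        null = _mean_metrics(fit_and_score(X, y_perm, idx_p, settings, seed=s_perm))
        for m in METRICS:
            if null[m] >= observed[m]:
                exceed[m] += 1

    table = pd.DataFrame(
        {
            "mean": observed,
            "ci_lower": ci.loc[0.025],
            "ci_upper": ci.loc[0.975],
            "p_value": {
                m: eq_permutation_pvalue(exceed[m], settings.n_permutations)
                for m in METRICS
            },
        }
    ).loc[list(METRICS)]
    return RfQualityReport(table=table, per_iteration=per_iter)


def permutation_pvalue(
    observed: float, X, y, metric: str = "auc",
    settings: RfSettings | None = None, K: int = 1000, seed: int | None = None,
) -> float:
    """Permutation p-value of one observed quality metric (see module docs)."""
    settings = settings or RfSettings()
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(K):
        y_perm = rng.permutation(y)
        idx = stratified_resample_indices(
            y_perm, settings.train_fraction, settings.n_resamples,
            seed=rng, min_class_size=settings.min_class_size,
        )
        null = _mean_metrics(fit_and_score(X, y_perm, idx, settings, seed=rng))
        if null[metric] >= observed:
            n_exceed += 1
    return eq_permutation_pvalue(n_exceed, K)


def gini_importance_with_pvalues(
    X, y, K: int = 1000, seed: int | None = None,
    settings: RfSettings | None = None, feature_names=None,
) -> pd.DataFrame:
    """Mean-decrease-Gini importance with per-variable permutation p-values.

    The forest is fitted on the full data; the null refits it on permuted
    labels K times and compares each variable's importance to its own null.
    Both uncorrected and Bonferroni-adjusted p-values are reported.
    """
    from .univariate import bonferroni

    settings = settings or RfSettings()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)

    def _importance(labels):
        forest = RandomForestClassifier(
            n_estimators=settings.n_estimators,
            max_features=settings.max_features,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(X, labels)
        return forest.feature_importances_

    observed = _importance(y)
    exceed = np.zeros(X.shape[1], dtype=int)
    for _ in range(K):
        exceed += _importance(rng.permutation(y)) >= observed
    p = np.array([eq_permutation_pvalue(int(e), K) for e in exceed])
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in range(X.shape[1])]
    )
    return pd.DataFrame(
        {
            "gini_importance": observed,
            "p_value": p,
            "p_adjusted": bonferroni(np.minimum(p, 1.0)),
        },
        index=names,
    )
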