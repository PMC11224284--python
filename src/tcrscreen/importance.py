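"""Feature-importance ranking and cross-method aggregation.

Tree-ensemble impurity importances (random forest, gradient boosting and a
subsampled/regularized boosting variant) and permutation importance
(accuracy drop under column shuffling) rank the features of any feature
matrix; ranks are aggregated across methods by summed importance and summed
rank.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.inspection import permutation_importance as _sk_permutation

from .classify import ClassifierSpec, make_estimator, make_pipeline
from .features import FeatureMatrix

MODEL_METHODS = ("rf", "gbdt", "xgboost_like")
_METHOD_TO_SPEC = {"rf": "random_forest", "gbdt": "gbdt", "xgboost_like": "xgboost_like"}


def model_importance(train: FeatureMatrix, method: str, seed: int = 0) -> np.ndarray:
    """Impurity-based importances, non-negative and normalized to sum 1,
    aligned with ``train.feature_names``."""
    if method not in _METHOD_TO_SPEC:
        raise ValueError(f"unknown method {method!r}; choose from {MODEL_METHODS}")
    if len(train.feature_names) == 1:
        return np.array([1.0])
    est = make_estimator(ClassifierSpec(_METHOD_TO_SPEC[method], seed=seed))
    est.fit(train.values, train.y())
    # impurity importances are non-negative up to float cancellation; clamp
    imp = np.maximum(np.asarray(est.feature_importances_, dtype=float), 0.0)
    total = imp.sum()
    if total <= 0:  # degenerate fit (e.g. constant features): no information
        return np.full(imp.shape, 1.0 / imp.size)
    return imp / total


def permutation_importance(
    model,
    data: FeatureMatrix,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean accuracy drop per feature over ``n_repeats`` column shuffles.

    Entries may be negative (shuffling a harmful feature can raise accuracy);
    a feature the model ignores gets exactly 0.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    res = _sk_permutation(
        model,
        data.values,
        data.y(),
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
    )
    return np.asarray(res.importances_mean, dtype=float)


def aggregate_importance(
    vectors: Sequence[np.ndarray], feature_names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(sum of importances, sum of per-method ranks) across methods.

    Ranks are 1 = most important per method; ties share the mean rank.  The
    aggregation is invariant to the order in which methods are supplied.
    """
    if not vectors:
        raise ValueError("no importance vectors supplied")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("importance vectors are not aligned on one feature list")
    stack = np.vstack([np.asarray(v, dtype=float) for v in vectors])
    if feature_names is not None and stack.shape[1] != len(feature_names):
        raise ValueError("importance vectors are not aligned with feature_names")
    sum_importance = stack.sum(axis=0)
    ranks = np.vstack([rankdata(-row, method="average") for row in stack])
    return sum_importance, ranks.sum(axis=0)


def rank_features(
    train: FeatureMatrix,
    methods: Sequence[str] = ("rf", "gbdt", "xgboost_like", "permutation"),
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """The diversity-index importance experiment: per-method importances plus
    the summed importance/rank aggregates, one row per feature.

    ``"permutation"`` uses accuracy-drop permutation importance on a
    random-forest classifier fitted to the same data.
    """
    columns: dict[str, np.ndarray] = {}
    for m in methods:
        if m == "permutation":
            model = make_pipeline(ClassifierSpec("random_forest", seed=seed))
            model.fit(train.values, train.y())
            columns[m] = permutation_importance(model, train, n_repeats=n_repeats, seed=seed)
        else:
            columns[m] = model_importance(train, m, seed=seed)
    sum_imp, sum_rank = aggregate_importance(list(columns.values()), train.feature_names)
    df = pd.DataFrame(columns, index=train.feature_names)
    df["sum_importance"] = sum_imp
    df["sum_rank"] = sum_rank
    return df.sort_values("sum_rank")
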