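"""Minimal core-marker panel selection.

Reduces a screened presence matrix to a small marker panel by three routes:

* L1-penalized logistic regression (Lasso-style sparsity over a strength path);
* recursive feature elimination with cross-validation (RFECV, step 1) over any
  base estimator exposing coefficients or importances;
* greedy one-by-one backward exclusion keeping cross-validated AUC within a
  tolerance of the running best.

All cross-validation is stratified 5-fold with a fixed shuffling seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE, RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

from .classify import ClassifierSpec, EvalResult, fit_evaluate, make_estimator, make_pipeline
from .features import FeatureMatrix

_SCORING = {"auc": "roc_auc", "accuracy": "accuracy"}


@dataclass
class SelectionResult:
    method: str
    selected_keys: list[str]
    cv_scores: list[float] = field(default_factory=list)
    final_eval: EvalResult | None = None
    trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected_keys:
            raise ValueError("selection produced an empty key set")


#: repeats per CV evaluation; AUC on ~9-sample folds is coarse, and exact
#: score ties would otherwise dominate the smallest-dimension tie rule.
#: the greedy exclusion loop compares scores of near-equivalent panels, so it
#: uses a finer estimate (cheap: its panels are small)
_CV_REPEATS = 3
_EXCLUSION_CV_REPEATS = 10


def _cv(cv_folds: int, seed: int, n_repeats: int = _CV_REPEATS) -> RepeatedStratifiedKFold:
    return RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=n_repeats,
                                   random_state=seed)


def lasso_select(
    train: FeatureMatrix,
    regularization: float | str = "cv",
    test: FeatureMatrix | None = None,
    classifier: ClassifierSpec | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Features with non-zero L1-logistic coefficients at the chosen strength.

    ``regularization`` is the inverse-strength C of the L1 logistic model
    ("cv" picks C by stratified cross-validated accuracy over a log grid).
    The coefficient path over the C grid is recorded in ``trace``.
    """
    if len(train.feature_names) < 2:
        raise ValueError("lasso selection needs at least 2 features")
    X, y = train.values, train.y()
    c_grid = np.logspace(-2, 2, 21)

    trace = []
    cv_scores = []
    for c in c_grid:
        model = LogisticRegression(
            l1_ratio=1, solver="liblinear", C=c, random_state=seed, max_iter=5000
        )
        score = float(cross_val_score(model, X, y, cv=_cv(cv_folds, seed)).mean())
        model.fit(X, y)
        coefs = model.coef_.ravel().tolist()
        trace.append({"C": float(c), "cv_accuracy": score, "coefficients": coefs})
        cv_scores.append(score)

    if regularization == "cv":
        best = int(np.argmax(cv_scores))
        chosen_c = float(c_grid[best])
    else:
        chosen_c = float(regularization)
    final = LogisticRegression(
        l1_ratio=1, solver="liblinear", C=chosen_c, random_state=seed, max_iter=5000
    ).fit(X, y)
    coef = final.coef_.ravel()
    order = np.argsort(-np.abs(coef))
    selected = [train.feature_names[i] for i in order if coef[i] != 0.0]
    if not selected:
        raise ValueError(
            f"all coefficients are zero at C={chosen_c:g}; use weaker regularization"
        )
    result = SelectionResult("lasso", selected, cv_scores=cv_scores, trace=trace)
    if test is not None and classifier is not None:
        result.final_eval = fit_evaluate(
            train.select_features(selected), test.select_features(selected), classifier
        )
    return result


def rfecv_select(
    train: FeatureMatrix,
    estimator: ClassifierSpec,
    cv_folds: int = 5,
    scoring: str = "auc",
    seed: int = 0,
    test: FeatureMatrix | None = None,
    classifier: ClassifierSpec | None = None,
) -> SelectionResult:
    """Recursive feature elimination (step 1) scored by cross-validation.

    The selected dimension is the smallest one attaining the maximum mean CV
    score (ties favour fewer features); ``cv_scores[i]`` is the mean CV score
    at dimension i+1.
    """
    if scoring not in _SCORING:
        raise ValueError(f"scoring must be one of {sorted(_SCORING)}")
    base = make_estimator(estimator)
    if not (hasattr(base, "coef_") or hasattr(base, "feature_importances_")
            or estimator.name in ("logistic", "svm_linear", "lda", "decision_tree",
                                  "random_forest", "gbdt", "xgboost_like", "adaboost")):
        # a fitted check would be cleaner, but RFE itself raises late and cryptically
        raise ValueError(f"estimator {estimator.name!r} exposes no feature-ranking signal")
    selector = RFECV(
        base,
        step=1,
        min_features_to_select=1,
        cv=_cv(cv_folds, seed),
        scoring=_SCORING[scoring],
    )
    selector.fit(train.values, train.y())
    mean_scores = selector.cv_results_["mean_test_score"].tolist()
    # dimension i+1 has score mean_scores[i]; smallest dimension at the max
    best_dim = int(np.argmax(mean_scores)) + 1
    rfe = RFE(make_estimator(estimator), n_features_to_select=best_dim, step=1)
    rfe.fit(train.values, train.y())
    selected = [n for n, keep in zip(train.feature_names, rfe.support_) if keep]
    result = SelectionResult(
        f"rfecv[{estimator.name}]",
        selected,
        cv_scores=mean_scores,
        trace=[{"dimension": i + 1, "mean_cv_score": s} for i, s in enumerate(mean_scores)],
    )
    if test is not None and classifier is not None:
        result.final_eval = fit_evaluate(
            train.select_features(selected), test.select_features(selected), classifier
        )
    return result


def _cv_auc(train: FeatureMatrix, keys: Sequence[str], spec: ClassifierSpec,
            cv_folds: int, seed: int) -> float:
    sub = train.select_features(keys)
    model = make_pipeline(spec)
    return float(
        cross_val_score(model, sub.values, sub.y(),
                        cv=_cv(cv_folds, seed, _EXCLUSION_CV_REPEATS),
                        scoring="roc_auc").mean()
    )


def backward_exclusion(
    train: FeatureMatrix,
    test: FeatureMatrix | None,
    start_keys: Sequence[str],
    spec: ClassifierSpec,
    tolerance: float = 0.0,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Greedy one-by-one exclusion: repeatedly drop the feature whose removal
    least harms (or most helps) train-CV AUC, while the score stays within
    ``tolerance`` of the running best.  Returns the smallest surviving set;
    the full exclusion trace is recorded.
    """
    current = list(start_keys)
    if not current:
        raise ValueError("start_keys is empty")
    missing = set(current) - set(train.feature_names)
    if missing:
        raise ValueError(f"start_keys not in feature set: {sorted(missing)}")

    best_score = _cv_auc(train, current, spec, cv_folds, seed)
    trace = [{"kept": list(current), "removed": None, "cv_auc": best_score}]
    while len(current) > 1:
        candidates = []
        for f in sorted(current):  # deterministic tie-break: lexicographic
            remaining = [k for k in current if k != f]
            candidates.append((_cv_auc(train, remaining, spec, cv_folds, seed), f))
        score, drop_feature = max(candidates, key=lambda t: (t[0], t[1]))
        if best_score - score > tolerance:
            break
        current = [k for k in current if k != drop_feature]
        best_score = max(best_score, score)
        trace.append({"kept": list(current), "removed": drop_feature, "cv_auc": score})

    result = SelectionResult("backward_exclusion", current, trace=trace)
    if test is not None:
        result.final_eval = fit_evaluate(
            train.select_features(current), test.select_features(current), spec
        )
    return result


def selection_grid(
    train: FeatureMatrix,
    test: FeatureMatrix,
    estimators: Sequence[ClassifierSpec],
    classifiers: Sequence[ClassifierSpec],
    seed: int = 0,
    cv_folds: int = 5,
    scoring: str = "auc",
) -> pd.DataFrame:
    """Full RFECV-estimator × evaluation-classifier grid.

    One row per (estimator, classifier): selected dimension plus held-out AUC,
    accuracy, sensitivity and specificity for the selected panel.
    """
    if not estimators or not classifiers:
        raise ValueError("estimator and classifier lists must be non-empty")
    rows = []
    for est in estimators:
        sel = rfecv_select(train, est, cv_folds=cv_folds, scoring=scoring, seed=seed)
        for clf in classifiers:
            ev = fit_evaluate(
                train.select_features(sel.selected_keys),
                test.select_features(sel.selected_keys),
                clf,
            )
            rows.append(
                {
                    "estimator": est.name,
                    "classifier": clf.name,
                    "dimension": len(sel.selected_keys),
                    "selected_keys": ",".join(sel.selected_keys),
                    **ev.as_row(),
                }
            )
    return pd.DataFrame(rows)
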