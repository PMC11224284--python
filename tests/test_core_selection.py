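import numpy as np
import pytest

from tcrscreen import (
    ClassifierSpec,
    FeatureMatrix,
    backward_exclusion,
    lasso_select,
    rfecv_select,
    selection_grid,
)


def planted_presence(seed, n=200, n_inf=3, n_noise=17,
                     p_case=0.7, p_ctrl=0.05, background=0.3):
    """0/1 feature matrix: n_inf presence features enriched in cases, the rest
    equally prevalent in both groups (the screened-matrix analog)."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = np.empty((n, n_inf + n_noise))
    for j in range(n_inf):
        X[:, j] = rng.random(n) < np.where(y == 1, p_case, p_ctrl)
    X[:, n_inf:] = rng.random((n, n_noise)) < background
    names = [f"inf{j}" for j in range(n_inf)] + [f"noise{j}" for j in range(n_noise)]
    labels = ["case" if v else "control" for v in y]
    return FeatureMatrix([f"s{i}" for i in range(n)], names, X.astype(float), labels)


INFORMATIVE = {"inf0", "inf1", "inf2"}


def test_lasso_recovers_planted_features():
    recovered = 0
    for seed in range(20):
        sel = lasso_select(planted_presence(seed), seed=seed)
        if INFORMATIVE <= set(sel.selected_keys):
            recovered += 1
    assert recovered >= 18


def test_lasso_unregularized_limit_selects_everything():
    fm = planted_presence(0, n=100, n_noise=5)
    sel = lasso_select(fm, regularization=1e6)
    assert set(sel.selected_keys) == set(fm.feature_names)


def test_lasso_strong_regularization_raises_when_all_zero():
    with pytest.raises(ValueError, match="weaker regularization"):
        lasso_select(planted_presence(0), regularization=1e-4)


def test_lasso_drops_duplicate_of_informative_feature():
    kept_single = 0
    for seed in range(10):
        fm = planted_presence(seed, n_noise=5)
        dup = fm.values[:, [0]]
        m = FeatureMatrix(fm.sample_ids, fm.feature_names + ["inf0_copy"],
                          np.hstack([fm.values, dup]), fm.labels)
        try:
            sel = lasso_select(m, regularization=0.03, seed=seed)
        except ValueError:
            kept_single += 1  # everything zeroed: the pair is trivially collapsed
            continue
        if len({"inf0", "inf0_copy"} & set(sel.selected_keys)) <= 1:
            kept_single += 1
    assert kept_single >= 7  # collinear pair is usually collapsed to one member


def test_rfecv_single_informative_feature_forces_dimension_one():
    fm = planted_presence(1, n=150, n_inf=1, n_noise=6, p_case=0.95, p_ctrl=0.02)
    sel = rfecv_select(fm, ClassifierSpec("logistic", seed=0), scoring="auc", seed=0)
    assert sel.selected_keys == ["inf0"]
    assert len(sel.cv_scores) == 7


def test_rfecv_dimension_is_smallest_argmax_of_trace():
    for seed in (0, 1, 2):
        fm = planted_presence(seed, n=120, n_noise=8)
        sel = rfecv_select(fm, ClassifierSpec("decision_tree", seed=seed), seed=seed)
        scores = np.array(sel.cv_scores)
        assert len(sel.selected_keys) == int(np.argmax(scores)) + 1


def test_rfecv_adaboost_recovers_planted():
    good = 0
    for seed in range(10):
        fm = planted_presence(seed)
        sel = rfecv_select(fm, ClassifierSpec("adaboost", seed=seed), seed=seed)
        if len(sel.selected_keys) <= 6 and INFORMATIVE <= set(sel.selected_keys):
            good += 1
    assert good >= 8


def test_rfecv_requires_ranking_signal():
    fm = planted_presence(0, n=60, n_noise=3)
    with pytest.raises(ValueError, match="ranking"):
        rfecv_select(fm, ClassifierSpec("knn"))


def test_backward_exclusion_collapses_redundant_copies():
    fm = planted_presence(2, n=200, n_inf=3, n_noise=0, p_case=0.9, p_ctrl=0.05)
    X = np.hstack([fm.values, fm.values[:, [0]], fm.values[:, [1]]])
    m = FeatureMatrix(fm.sample_ids, ["a", "b", "c", "a_copy", "b_copy"], X, fm.labels)
    # a tree ignores one of two identical columns, so removing the unused
    # duplicate is exactly score-neutral and survives the tolerance-0 rule
    sel = backward_exclusion(m, None, m.feature_names, ClassifierSpec("decision_tree"),
                             tolerance=0.0)
    assert len(sel.selected_keys) <= 3
    # removals recorded in the trace never lose CV AUC beyond tolerance
    best = sel.trace[0]["cv_auc"]
    for step in sel.trace[1:]:
        assert step["cv_auc"] >= best - 1e-12
        best = max(best, step["cv_auc"])


def test_backward_exclusion_infinite_tolerance_runs_to_one_feature():
    fm = planted_presence(3, n=100, n_noise=4)
    sel = backward_exclusion(fm, None, fm.feature_names, ClassifierSpec("logistic"),
                             tolerance=np.inf)
    assert len(sel.selected_keys) == 1
    # surviving sets form a subset chain of the start set
    kept = [set(step["kept"]) for step in sel.trace]
    assert all(b < a for a, b in zip(kept, kept[1:]))


def test_backward_exclusion_keeps_jointly_necessary_features():
    # y is the majority vote of three ±1 features: every feature is necessary,
    # so at tolerance 0 the start set survives intact
    rng = np.random.default_rng(0)
    X = rng.choice([-1.0, 1.0], size=(240, 3))
    y = (X.sum(axis=1) > 0).astype(int)
    m = FeatureMatrix([f"s{i}" for i in range(240)], ["a", "b", "c"], X,
                      ["case" if v else "control" for v in y])
    sel = backward_exclusion(m, None, ["a", "b", "c"], ClassifierSpec("logistic"),
                             tolerance=0.0)
    assert sel.selected_keys == ["a", "b", "c"]


def test_backward_exclusion_empty_start_rejected():
    fm = planted_presence(0, n=60, n_noise=3)
    with pytest.raises(ValueError):
        backward_exclusion(fm, None, [], ClassifierSpec("logistic"))


def test_selection_grid_shape_determinism_and_signal():
    train = planted_presence(4, n=120, n_noise=7)
    test = planted_presence(104, n=60, n_noise=7)
    estimators = [ClassifierSpec("logistic"), ClassifierSpec("decision_tree")]
    classifiers = [ClassifierSpec("svm_linear"), ClassifierSpec("naive_bayes")]
    g1 = selection_grid(train, test, estimators, classifiers, seed=0)
    g2 = selection_grid(train, test, estimators, classifiers, seed=0)
    assert len(g1) == 4
    assert g1["auc"].between(0, 1).all()
    assert g1.equals(g2)
    assert g1["auc"].max() >= 0.9  # strong planted signal is recoverable
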