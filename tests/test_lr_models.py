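"""Logistic-regression protocol: context selection, balanced weighting,
repeated stratified CV, decision boundaries, restricted refits, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.metrics import roc_auc_score

import confaudit as ca
from confaudit.lr_models import ModelConfig, FittedLinearModel


def toy_frame(X, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


# ------------------------------------------------------------ select_context


def test_screening_context_keeps_healthy_and_cancer(paper_cohort):
    _, table, meta = paper_cohort
    midx = meta.set_index("sample_id")
    disc = table.subset_samples([s for s in table.sample_ids if midx.loc[s, "cohort"] == "discovery"])
    sub, labels = ca.select_context(disc, meta, "screening")
    assert len(labels) == 276 and labels.sum() == 94
    conditions = midx.loc[sub.sample_ids, "condition"]
    assert "benign" not in set(conditions)


def test_diagnostic_context_excludes_healthy(paper_cohort):
    _, table, meta = paper_cohort
    sub, labels = ca.select_context(table, meta, "diagnostic")
    conditions = meta.set_index("sample_id").loc[sub.sample_ids, "condition"]
    assert set(conditions) == {"benign", "cancer"}


def test_missing_class_is_an_error(paper_cohort):
    _, table, meta = paper_cohort
    no_benign = meta[meta.condition != "benign"]
    sub = table.subset_samples(list(no_benign.sample_id))
    with pytest.raises(ValueError, match="benign"):
        ca.select_context(sub, no_benign, "diagnostic")


# --------------------------------------------------------------------- fit


def test_separable_toy_set_reaches_training_auc_one():
    X = toy_frame([[0, 0], [0, 1], [3, 3], [3, 4]])
    y = np.array([0, 0, 1, 1], dtype=bool)
    model = ca.fit(X, y, ModelConfig())
    assert roc_auc_score(y, model.predict_proba(X.to_numpy())) == 1.0


def test_constant_feature_gets_zero_coefficient(rng):
    X = toy_frame(np.column_stack([rng.normal(size=40), np.full(40, 2.0)]))
    y = X["f0"].to_numpy() + 0.3 * rng.normal(size=40) > 0
    model = ca.fit(X, y, ModelConfig())
    assert abs(model.coefficients[1]) < 1e-6


def _direct_objective(Xb, y, weights, C):
    """Independent oracle: minimize 0.5||w||^2 + C * sum_i w_i * logloss_i."""
    def obj(params):
        w, b = params[:-1], params[-1]
        lp = Xb @ w + b
        ll = np.logaddexp(0, lp) - y * lp
        return 0.5 * w @ w + C * (weights * ll).sum()

    best = None
    for x0_seed in (0, 1):
        start = np.zeros(Xb.shape[1] + 1) if x0_seed == 0 else np.random.default_rng(x0_seed).normal(size=Xb.shape[1] + 1)
        res = minimize(obj, start, method="L-BFGS-B", tol=1e-14)
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def test_balanced_weights_equal_minority_duplication(rng):
    """Balanced class weights with penalty weight C match an unweighted fit
    on minority-duplicated data once C is rescaled by n/(2*n_majority) — the
    balanced weights change the total error mass but not the L2 penalty.
    Both sklearn routes are also checked against direct minimization of the
    written objective."""
    n_min, n_maj = 15, 30
    X = np.vstack(
        [rng.normal(loc=1.0, size=(n_min, 2)), rng.normal(loc=0.0, size=(n_maj, 2))]
    )
    y = np.r_[np.ones(n_min, dtype=bool), np.zeros(n_maj, dtype=bool)]
    n = n_min + n_maj
    scale = n / (2 * n_maj)

    balanced = ca.fit(toy_frame(X), y, ModelConfig(class_weight="balanced", C=1.0))
    dup_X = np.vstack([X, X[:n_min]])
    dup_y = np.r_[y, np.ones(n_min, dtype=bool)]
    duplicated = ca.fit(
        toy_frame(dup_X), dup_y, ModelConfig(class_weight=None, C=scale)
    )
    np.testing.assert_allclose(balanced.coefficients, duplicated.coefficients, atol=1e-5)
    assert balanced.intercept == pytest.approx(duplicated.intercept, abs=1e-5)

    weights = np.where(y, n / (2 * n_min), n / (2 * n_maj))
    direct = _direct_objective(X, y.astype(float), weights, C=1.0)
    np.testing.assert_allclose(balanced.coefficients, direct[:-1], atol=1e-4)
    assert balanced.intercept == pytest.approx(direct[-1], abs=1e-4)


def test_fit_is_deterministic_and_matches_fresh_solver(rng):
    X = toy_frame(rng.normal(size=(60, 3)))
    y = (X.sum(axis=1) + rng.normal(scale=0.5, size=60) > 0).to_numpy()
    m1 = ca.fit(X, y, ModelConfig(seed=0))
    m2 = ca.fit(X, y, ModelConfig(seed=99))
    np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-8)


def test_fit_rejects_tiny_classes():
    X = toy_frame([[0.0], [1.0], [2.0]])
    with pytest.raises(ValueError):
        ca.fit(X, np.array([True, False, False]), ModelConfig())


def test_standardize_flag_returns_raw_scale_coefficients(rng):
    """With standardization on, coefficients are folded back to the raw
    feature scale, so predictions match applying the model to raw inputs."""
    X = toy_frame(np.column_stack([rng.normal(scale=10, size=80), rng.normal(size=80)]))
    y = (X["f0"] / 10 + X["f1"] + rng.normal(scale=0.5, size=80) > 0).to_numpy()
    model = ca.fit(X, y, ModelConfig(standardize=True))
    manual = expit(X.to_numpy() @ model.coefficients + model.intercept)
    np.testing.assert_allclose(model.predict_proba(X.to_numpy()), manual)


# -------------------------------------------------------------- repeated CV


def cv_toy(rng, n=40):
    X = toy_frame(rng.normal(size=(n, 2)))
    y = (X["f0"] + rng.normal(scale=0.8, size=n) > 0).to_numpy()
    return X, y


def test_every_sample_held_out_once_per_repeat(rng):
    X, y = cv_toy(rng)
    config = ModelConfig(cv_folds=4, cv_repeats=3, seed=1)
    scores = ca.repeated_stratified_cv(X, y, config)
    per_repeat = scores.fold_assignments.groupby(["repeat", "sample_id"]).size()
    assert (per_repeat == 1).all()
    assert scores.fold_assignments["repeat"].nunique() == 3


def test_cv_scores_are_out_of_fold(rng):
    """Recomputing repeat 0 by hand (same fold partition, independent fits)
    reproduces the protocol's held-out scores."""
    from sklearn.model_selection import StratifiedKFold

    X, y = cv_toy(rng)
    config = ModelConfig(cv_folds=4, cv_repeats=1, seed=3)
    scores = ca.repeated_stratified_cv(X, y, config)
    skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=3)
    manual = np.zeros(len(y))
    for train, test in skf.split(np.zeros(len(y)), y.astype(int)):
        model = ca.fit(X.iloc[train], y[train], config)
        manual[test] = model.predict_proba(X.iloc[test].to_numpy())
    np.testing.assert_allclose(scores.mean_scores, manual)


def test_identically_seeded_cv_runs_agree(rng):
    X, y = cv_toy(rng)
    config = ModelConfig(cv_folds=5, cv_repeats=2, seed=8)
    s1 = ca.repeated_stratified_cv(X, y, config)
    s2 = ca.repeated_stratified_cv(X, y, config)
    np.testing.assert_array_equal(s1.mean_scores, s2.mean_scores)


def test_cv_rejects_class_smaller_than_k():
    X = toy_frame(np.arange(12, dtype=float).reshape(-1, 1))
    y = np.array([True] * 3 + [False] * 9)
    with pytest.raises(ValueError, match="smaller than k"):
        ca.repeated_stratified_cv(X, y, ModelConfig(cv_folds=5))


def test_scores_stay_in_unit_interval_and_auc_is_rank_invariant(rng):
    X, y = cv_toy(rng, n=60)
    scores = ca.repeated_stratified_cv(X, y, ModelConfig(cv_repeats=2, seed=2))
    assert ((scores.mean_scores > 0) & (scores.mean_scores < 1)).all()
    auc = roc_auc_score(scores.labels, scores.mean_scores)
    logit = np.log(scores.mean_scores / (1 - scores.mean_scores))
    assert roc_auc_score(scores.labels, logit) == pytest.approx(auc)


# -------------------------------------------------------- decision boundary


@pytest.mark.parametrize(
    "w,b,slope,intercept",
    [
        ((1.25, 1.02), -2.22, -1.23, None),
        ((0.14, 1.15), -1.66, -0.12, None),
        ((1.0, 1.0), 0.0, -1.0, 0.0),
    ],
)
def test_decision_boundary_slopes(w, b, slope, intercept):
    """The screening model's printed coefficients give a boundary slope of
    -1.23; the diagnostic model's give the much flatter -0.12."""
    s, i = ca.decision_boundary(FittedLinearModel(np.array(w), b, ("x", "y")))
    assert round(s, 2) == slope
    if intercept is not None:
        assert i == pytest.approx(intercept)


def test_decision_boundary_requires_two_features_and_nonzero_w2():
    with pytest.raises(ValueError):
        ca.decision_boundary(FittedLinearModel(np.array([1.0]), 0.0, ("x",)))
    with pytest.raises(ValueError):
        ca.decision_boundary(FittedLinearModel(np.array([1.0, 0.0]), 0.0, ("x", "y")))


# -------------------------------------------------------- restricted refits


def test_restriction_drops_exactly_the_42_affected_cancers(paper_cohort):
    _, table, meta = paper_cohort
    config = ModelConfig(context="screening", features=("zlog_CA125", "zlog_HE4"), cv_repeats=1, seed=0)
    _, cv_full = ca.train_context_model(table, meta, config)
    _, cv_restr = ca.restrict_and_refit(table, meta, "PGDX", config)
    assert cv_full.labels.sum() - cv_restr.labels.sum() == 42
    assert len(cv_full.labels) - len(cv_restr.labels) == 42  # no healthy removed


def test_restricting_an_absent_prefix_is_a_noop(paper_cohort):
    _, table, meta = paper_cohort
    config = ModelConfig(context="screening", features=("zlog_CA125", "zlog_HE4"), cv_repeats=1, seed=0)
    model_a, _ = ca.train_context_model(table, meta, config)
    model_b, _ = ca.restrict_and_refit(table, meta, "NOSUCH", config)
    np.testing.assert_allclose(model_a.coefficients, model_b.coefficients, atol=1e-10)


def test_restriction_that_empties_a_class_errors(paper_cohort):
    _, table, meta = paper_cohort
    with pytest.raises(ValueError, match="CGPL"):
        ca.restrict_and_refit(table, meta, "CGPL", ModelConfig(context="screening"))


# ------------------------------------------------------------ score_external


def test_null_model_scores_half_everywhere():
    model = FittedLinearModel(np.zeros(2), 0.0, ("a", "b"))
    frame = toy_frame(np.random.default_rng(0).normal(size=(5, 2)), ["a", "b"])
    assert (ca.score_external(model, frame) == 0.5).all()


def test_published_ca125_model_scores_its_threshold_zlog():
    """The single-marker model with coefficient 1.39 and intercept -1.84
    scores ~0.88 at a zlog value of 2.78 — the printed threshold chain."""
    model = FittedLinearModel(np.array([1.39]), -1.84, ("zlog_CA125",))
    score = ca.score_external(model, toy_frame([[2.78]], ["zlog_CA125"]))
    assert score.iloc[0] == pytest.approx(0.88, abs=0.005)


def test_scoring_requires_model_features():
    model = FittedLinearModel(np.array([1.0]), 0.0, ("present",))
    with pytest.raises(KeyError, match="missing"):
        ca.score_external(model, toy_frame([[1.0]], ["other"]))


def test_model_json_round_trip():
    model = FittedLinearModel(np.array([1.25, 1.02]), -2.22, ("zlog_CA125", "zlog_HE4"), np.array([1.4, 1.3]))
    back = FittedLinearModel.from_json(model.to_json())
    np.testing.assert_array_equal(back.coefficients, model.coefficients)
    assert back.feature_names == model.feature_names
    np.testing.assert_array_equal(back.training_sds, model.training_sds)
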