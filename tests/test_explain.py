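"""Additive attribution contracts and bit -> substructure mapping."""

import numpy as np
import pytest

from dualqsar.explain import (
    ExplainError,
    additivity_check,
    attribution_summary,
    bit_to_fragment,
    linear_attributions,
    tree_attributions,
)


def test_attribution_summary_hand_matrix():
    contribs = np.array([[1.0, -0.1], [0.5, -0.3], [1.5, -0.2]])
    rep = attribution_summary(contribs, base=0.2, feature_names=["a", "b"])
    assert rep.ranking == ["a", "b"]  # mean |a| = 1.0 > mean |b| = 0.2
    assert rep.mean_abs["a"] == pytest.approx(1.0)
    assert rep.mean_abs["b"] == pytest.approx(0.2)
    assert rep.direction["a"] == 1 and rep.direction["b"] == -1
    rep2 = attribution_summary(np.zeros((3, 2)), 0.0)
    assert rep2.ranking == []


def test_attribution_direction_over_carriers():
    """With feature values supplied, direction comes from the carrier
    rows only (the all-rows mean of a split feature's contributions is
    ~0 by construction)."""
    X = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    contribs = np.array([[0.9, 0.1], [-0.45, -0.6], [-0.45, -0.6]])
    rep = attribution_summary(contribs, 0.0, ["a", "b"], feature_values=X)
    assert rep.direction["a"] == 1    # carriers of a gain +0.9
    assert rep.direction["b"] == -1   # carriers of b lose -0.6
    with pytest.raises(ExplainError):
        attribution_summary(contribs, 0.0, ["a", "b"],
                            feature_values=X[:, :1])


def test_attribution_summary_single_dominant_feature():
    contribs = np.zeros((5, 4))
    contribs[:, 2] = -2.0
    rep = attribution_summary(contribs, 0.0)
    assert rep.ranking[0] == "f2"
    assert rep.direction["f2"] == -1
    with pytest.raises(ExplainError):
        attribution_summary(contribs, 0.0, feature_names=["x"])


@pytest.mark.parametrize("model_cls, kwargs", [
    ("DecisionTreeRegressor", {"max_depth": 4}),
    ("RandomForestRegressor", {"n_estimators": 30}),
    ("GradientBoostingRegressor", {"n_estimators": 50}),
])
def test_tree_attributions_exactly_additive(model_cls, kwargs):
    import sklearn.ensemble as ens
    import sklearn.tree as tree

    cls = getattr(ens, model_cls, None) or getattr(tree, model_cls)
    rng = np.random.default_rng(0)
    X = (rng.random((120, 8)) < 0.5).astype(float)
    y = 2 * X[:, 0] - 1.5 * X[:, 1] + rng.normal(0, 0.1, 120)
    model = cls(random_state=0, **kwargs).fit(X, y)
    contribs, base, pred = tree_attributions(model, X)
    assert additivity_check(contribs, base, pred, tol=1e-6).all()


def test_tree_attributions_classifier_probability_space():
    from sklearn.ensemble import RandomForestClassifier

    rng = np.random.default_rng(1)
    X = (rng.random((100, 6)) < 0.5).astype(float)
    y = (X[:, 0] + rng.normal(0, 0.2, 100) > 0.5).astype(int)
    model = RandomForestClassifier(n_estimators=40, random_state=0).fit(X, y)
    contribs, base, pred = tree_attributions(model, X)
    assert np.allclose(pred, model.predict_proba(X)[:, 1])
    assert additivity_check(contribs, base, pred).all()


def test_gradient_boosting_classifier_margin_space():
    from sklearn.ensemble import GradientBoostingClassifier

    rng = np.random.default_rng(2)
    X = (rng.random((100, 6)) < 0.5).astype(float)
    y = (X[:, 0].astype(int) ^ (rng.random(100) < 0.1)).astype(int)
    model = GradientBoostingClassifier(n_estimators=40,
                                       random_state=0).fit(X, y)
    contribs, base, pred = tree_attributions(model, X)
    assert np.allclose(pred, model.decision_function(X))
    assert additivity_check(contribs, base, pred).all()


def test_linear_attributions_additive():
    from sklearn.linear_model import LinearRegression

    rng = np.random.default_rng(3)
    X = rng.normal(size=(50, 4))
    y = X @ np.array([1.0, -2.0, 0.0, 0.5]) + 3.0
    model = LinearRegression().fit(X, y)
    contribs, base, pred = linear_attributions(model, X, background=X)
    assert additivity_check(contribs, base, pred, tol=1e-8).all()


def test_constant_model_all_contributions_zero():
    from sklearn.tree import DecisionTreeRegressor

    X = np.ones((10, 3))
    y = np.full(10, 2.5)
    model = DecisionTreeRegressor().fit(X, y)
    contribs, base, pred = tree_attributions(model, X)
    assert np.allclose(contribs, 0.0)
    assert base == pytest.approx(2.5)


def test_corrupted_contribution_row_fails_check():
    contribs = np.zeros((3, 2))
    pred = np.zeros(3)
    contribs[1, 0] = 0.5  # corrupt one row
    flags = additivity_check(contribs, 0.0, pred)
    assert flags.tolist() == [True, False, True]
    with pytest.raises(ExplainError):
        additivity_check(contribs, 0.0, np.zeros(4))


def test_unsupported_model_rejected():
    from sklearn.svm import SVC

    X = np.random.default_rng(4).normal(size=(20, 3))
    y = (X[:, 0] > 0).astype(int)
    with pytest.raises(ExplainError):
        tree_attributions(SVC().fit(X, y), X)


def test_benzene_ecfp_bit_maps_to_aromatic_environment():
    from dualqsar.featurize import compute_fingerprints

    fps = compute_fingerprints(["c1ccccc1"], "ECFP6")
    bit = int(np.flatnonzero(fps.matrix[0])[0])
    rec = bit_to_fragment("c1ccccc1", bit, "ECFP6")
    assert rec.environments
    assert all(env["aromatic"] for env in rec.environments)


def test_maccs_bit_returns_predefined_smarts():
    # key 162 is the aromaticity key; benzene sets it
    rec = bit_to_fragment("c1ccccc1", 162, "MACCS")
    assert rec.smarts is not None
    assert rec.environments


def test_bit_not_set_errors():
    from dualqsar.featurize import compute_fingerprints

    fps = compute_fingerprints(["CC"], "ECFP6")
    unset = int(np.flatnonzero(fps.matrix[0] == 0)[0])
    with pytest.raises(ExplainError):
        bit_to_fragment("CC", unset, "ECFP6")


def test_planted_fragment_sign_recovery_noiseless():
    """Attribution signs match planted weights for >=8/10 top fragments."""
    from dualqsar.pipeline import recover_fragment_signs
    from dualqsar.synthetic import GeneratorConfig, generate_library

    _, _, truth = generate_library(
        GeneratorConfig(n_compounds=300, seed=0, noise_sd=0.0))
    for target in ("ache", "bace"):
        agree, k = recover_fragment_signs(truth, target)
        assert k == 10
        assert agree >= 8
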