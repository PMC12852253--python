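"""Resampling, metric panels, ranking, and leakage-safe benchmarking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualqsar.benchmark import (
    BenchmarkError,
    MetricReport,
    RankingWeights,
    benchmark_models,
    best_f1_threshold,
    classification_metrics,
    fit_classifier,
    hierarchical_rank,
    regression_metrics,
    smote_oversample,
    smote_tomek,
    tomek_links,
    weighted_score,
)


# ------------------------------------------------------------- resampling

def test_smote_points_lie_on_minority_segments():
    """Convexity: every synthetic point is on a segment between the two
    minority originals (the only neighbour pair available)."""
    X = np.array([[0.0, 0.0], [1.0, 1.0],
                  [5.0, 5.0], [6.0, 5.0], [7.0, 5.0], [8.0, 5.0]])
    y = np.array([1, 1, 0, 0, 0, 0])
    Xo, yo = smote_oversample(X, y, seed=0)
    synth = Xo[len(X):]
    assert len(synth) == 2  # balances 2 vs 4
    for s in synth:
        # on the segment (0,0)-(1,1): x == y and 0 <= x <= 1
        assert s[0] == pytest.approx(s[1], abs=1e-12)
        assert -1e-12 <= s[0] <= 1 + 1e-12
    assert (yo[len(X):] == 1).all()


def test_smote_convexity_bulk():
    rng = np.random.default_rng(0)
    Xmin = rng.normal(0, 1, (20, 3))
    Xmaj = rng.normal(10, 1, (1020, 3))
    X = np.vstack([Xmin, Xmaj])
    y = np.array([1] * 20 + [0] * 1020)
    Xo, yo = smote_oversample(X, y, seed=1)
    synth = Xo[len(X):]
    assert len(synth) == 1000
    lo, hi = Xmin.min(axis=0), Xmin.max(axis=0)
    assert (synth >= lo - 1e-9).all() and (synth <= hi + 1e-9).all()


def test_smote_minority_of_one_errors():
    X = np.array([[0.0], [1.0], [2.0]])
    y = np.array([1, 0, 0])
    with pytest.raises(BenchmarkError):
        smote_oversample(X, y)


def test_tomek_removes_borderline_majority_member():
    """Hand-built NN structure: A(min) and B(maj) are mutual nearest
    neighbours, so B goes; the far majority pair C,D stays."""
    X = np.array([[0.0, 0.0], [0.2, 0.0], [5.0, 0.0], [5.2, 0.0],
                  [9.0, 0.0]])
    y = np.array([1, 0, 0, 0, 0])
    assert tomek_links(X, y) == [1]


def test_smote_tomek_balanced_no_links_unchanged():
    X = np.array([[0.0, 0], [0.1, 0], [5.0, 0], [5.1, 0]])
    y = np.array([1, 1, 0, 0])
    Xo, yo = smote_tomek(X, y, seed=0)
    assert sorted(map(tuple, Xo.tolist())) == sorted(map(tuple, X.tolist()))
    assert len(yo) == 4


# ---------------------------------------------------------------- metrics

def test_perfect_prediction_metrics_all_one():
    rep = classification_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
    for name in ("accuracy", "precision", "recall", "f1", "mcc",
                 "roc_auc", "pr_auc"):
        assert getattr(rep, name) == pytest.approx(1.0)


def test_four_point_confusion_matrix_enumeration():
    rep = classification_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1],
                                 threshold=0.5)
    assert rep.precision == pytest.approx(0.5)
    assert rep.recall == pytest.approx(0.5)
    assert rep.f1 == pytest.approx(0.5)
    assert rep.accuracy == pytest.approx(0.5)
    assert rep.mcc == pytest.approx(0.0)


def test_random_scores_give_half_auc():
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 100)
    aucs = [classification_metrics(y, rng.random(200)).roc_auc
            for _ in range(10)]
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_single_class_flags_auc_undefined():
    rep = classification_metrics([1, 1, 1], [0.2, 0.5, 0.9])
    assert np.isnan(rep.roc_auc) and np.isnan(rep.pr_auc)


def test_best_f1_threshold_brute_force():
    y = [1, 1, 0, 0]
    s = [0.9, 0.4, 0.6, 0.1]
    t, f1 = best_f1_threshold(y, s)
    # enumerate all 4 cut-points by hand: best is t=0.4 with F1=0.8
    assert (t, f1) == (pytest.approx(0.4), pytest.approx(0.8))


def test_best_f1_separable_and_constant_scores():
    t, f1 = best_f1_threshold([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
    assert f1 == 1.0 and 0.2 < t <= 0.8
    t, f1 = best_f1_threshold([0, 1], [0.5, 0.5])
    assert t == 0.5  # all-positive prediction at that score
    assert f1 == pytest.approx(2 / 3)


def _rep(**kw):
    base = dict(accuracy=0.9, precision=0.7, recall=1.0, f1=0.84,
                mcc=0.81, roc_auc=0.96, pr_auc=0.86)
    base.update(kw)
    return MetricReport(**base)


def test_weighted_score_values():
    assert weighted_score(_rep(f1=1, pr_auc=1, mcc=1, recall=1)) == \
        pytest.approx(1.0)
    assert weighted_score(_rep(f1=0, pr_auc=0, mcc=0, recall=0)) == 0.0
    # the winning gradient-boosting row: 0.4*0.84+0.3*0.86+0.2*0.81+0.1*1
    assert weighted_score(_rep()) == pytest.approx(0.856)


def test_weighted_score_missing_metric_errors():
    with pytest.raises(BenchmarkError):
        weighted_score(_rep(pr_auc=float("nan")))
    with pytest.raises(BenchmarkError):
        RankingWeights(w_f1=0.5, w_prauc=0.5, w_mcc=0.2, w_recall=0.1)


@given(st.floats(0, 1), st.floats(0, 1))
@settings(max_examples=50, deadline=None)
def test_weighted_score_monotone_in_f1(f1a, f1b):
    lo, hi = sorted([f1a, f1b])
    assert (weighted_score(_rep(f1=lo)) <= weighted_score(_rep(f1=hi)))


def test_hierarchical_rank_recall_first_then_weighted():
    winner = _rep(recall=1.0, f1=0.84, pr_auc=0.86, mcc=0.81)   # lower F1
    runner = _rep(recall=0.75, f1=0.85, pr_auc=0.87, mcc=0.84)  # higher F1
    ranked = hierarchical_rank([runner, winner])
    assert ranked[0] is winner
    # equal recall: ordered by weighted score
    a = _rep(recall=0.9, f1=0.8, pr_auc=0.8, mcc=0.7)
    b = _rep(recall=0.9, f1=0.9, pr_auc=0.9, mcc=0.8)
    assert hierarchical_rank([a, b])[0] is b
    assert hierarchical_rank([a]) == [a]


# ------------------------------------------------------------- regression

def test_regression_metrics_hand_example():
    rep = regression_metrics([1, 2, 3], [1, 2, 4])
    assert rep.mae == pytest.approx(1 / 3)
    assert rep.mse == pytest.approx(1 / 3)
    assert rep.r2 == pytest.approx(0.5)


def test_regression_perfect_and_mean_predictor():
    rep = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert rep.r2 == 1.0 and rep.mae == 0.0 and rep.mse == 0.0
    rep = regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    assert rep.r2 == pytest.approx(0.0)
    rep = regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    assert np.isnan(rep.r2)


def test_regression_q2_and_external():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(80, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.1, 80)
    from sklearn.linear_model import LinearRegression
    model = LinearRegression().fit(X, y)
    rep = regression_metrics(y, model.predict(X), model=model, X=X, y=y,
                             y_true_ext=y[:20], y_pred_ext=model.predict(X[:20]))
    assert rep.q2 is not None and rep.q2 > 0.9
    assert rep.r2_ext > 0.9 and rep.mse_ext >= 0


# ------------------------------------------------------------ benchmarking

def test_benchmark_table_shape_and_determinism(dual_features):
    X, y = dual_features
    from sklearn.ensemble import GradientBoostingClassifier, \
        RandomForestClassifier
    specs = {
        "GBDT": (GradientBoostingClassifier(random_state=0,
                                            n_estimators=60), {}),
        "RF": (RandomForestClassifier(random_state=0, n_estimators=60,
                                      class_weight="balanced"), {}),
    }
    feats = {"ECFP6": X, "ECFP6_prefix": X[:, :256]}
    df1, reports, fitted = benchmark_models(feats, y, model_specs=specs,
                                            seed=0)
    df2, _, _ = benchmark_models(feats, y, model_specs=specs, seed=0)
    assert len(df1) == len(specs) * len(feats)
    assert df1.drop(columns=["rank"]).equals(df2.drop(columns=["rank"]))
    assert set(df1["rank"]) == set(range(1, len(df1) + 1))


def test_benchmark_separable_synthetic_high_recall():
    """Planted noiseless (strongly separable) activity: the boosted-tree
    model recovers essentially all dual actives in the hold-out."""
    from sklearn.ensemble import GradientBoostingClassifier

    from dualqsar import curation
    from dualqsar.featurize import compute_fingerprints
    from dualqsar.synthetic import GeneratorConfig, generate_library
    from tests.conftest import ecfp

    ache, bace, _ = generate_library(GeneratorConfig(
        n_compounds=250, overlap_fraction=1.0, noise_sd=0.0, seed=8))
    curation.curate(ache, ecfp)
    curation.curate(bace, ecfp)
    dual = curation.build_dual_dataset(ache, bace)
    smiles = {r.compound_id: r.smiles for r in ache.kept_records()}
    sm = [smiles[c] for c in dual.compound_ids]
    feats = {k: compute_fingerprints(sm, k).matrix.astype(float)
             for k in ("ECFP6", "MACCS")}
    specs = {"GBDT": (GradientBoostingClassifier(random_state=0,
                                                 n_estimators=100), {})}
    df, reports, _ = benchmark_models(feats, dual.labels,
                                      model_specs=specs, seed=0)
    assert df["recall"].max() >= 0.9


def test_label_shuffle_leakage_canary(canary_features):
    """Resampling inside the training fold only: shuffled labels must
    give hold-out MCC ~ 0 (mean |MCC| < 0.15 over 10 seeds)."""
    from sklearn.ensemble import GradientBoostingClassifier
    from sklearn.model_selection import train_test_split

    X, y = canary_features
    mccs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        ys = rng.permutation(y)
        idx = np.arange(len(ys))
        tr, te = train_test_split(idx, test_size=0.25, stratify=ys,
                                  random_state=seed)
        model = fit_classifier(
            X[tr], ys[tr],
            GradientBoostingClassifier(random_state=seed, n_estimators=60),
            seed=seed, resample=True)
        rep = classification_metrics(ys[te],
                                     model.predict_proba(X[te])[:, 1])
        mccs.append(abs(rep.mcc))
    assert float(np.mean(mccs)) < 0.15
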