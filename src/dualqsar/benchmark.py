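"""Imbalance-aware model benchmarking with a composite ranking score.

Six classifier families (KNN, SVM, RF, GBDT and - when installed -
LightGBM/XGBoost boosted trees) are trained per feature set on a
stratified hold-out split.  Class weights are balanced where the
estimator supports it and SMOTE+Tomek resampling is applied to the
training fold only; hyper-parameters come from a small grid search with
5-fold CV inside the training data.

Model ranking is hierarchical: recall for the positive (dual-inhibitor)
class first, then a weighted composite

    score = 0.4*F1 + 0.3*PR-AUC + 0.2*MCC + 0.1*Recall.

SMOTE here generates synthetic minority points x + lam*(x' - x) with
lam ~ U(0,1) toward one of the k=5 nearest minority neighbours; the
Tomek step removes majority members of cross-class mutual-nearest-
neighbour pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    mean_absolute_error,
    mean_squared_error,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC
from sklearn.base import clone


class BenchmarkError(ValueError):
    pass


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def smote_oversample(X, y, seed=0, k_neighbors: int = 5, n_synthetic=None):
    """SMOTE: synthesize minority points on segments between neighbours."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise BenchmarkError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    Xmin = X[y == minority]
    if len(Xmin) < 2:
        raise BenchmarkError("minority class needs >= 2 samples for SMOTE")
    if n_synthetic is None:
        n_synthetic = int(counts.max() - counts.min())
    if n_synthetic <= 0:
        return X, y
    k = min(k_neighbors, len(Xmin) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xmin), size=n_synthetic)
    pick = rng.integers(1, k + 1, size=n_synthetic)
    lam = rng.uniform(0.0, 1.0, size=n_synthetic)
    neigh = Xmin[idx[base, pick]]
    synth = Xmin[base] + lam[:, None] * (neigh - Xmin[base])
    Xo = np.vstack([X, synth])
    yo = np.concatenate([y, np.full(n_synthetic, minority, dtype=y.dtype)])
    return Xo, yo


def tomek_links(X, y):
    """Indices of majority-class members of cross-class mutual-NN pairs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise BenchmarkError("Tomek links require two classes")
    majority = classes[np.argmax(counts)]
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    _, idx = nn.kneighbors(X)
    nearest = idx[:, 1]
    remove = set()
    for i in range(len(X)):
        j = nearest[i]
        if nearest[j] == i and y[i] != y[j]:  # mutual NN, opposite classes
            for m in (i, j):
                if y[m] == majority:
                    remove.add(int(m))
    return sorted(remove)


def smote_tomek(X, y, seed=0, k_neighbors: int = 5):
    """SMOTE oversampling followed by Tomek-link cleaning of the majority."""
    Xo, yo = smote_oversample(X, y, seed=seed, k_neighbors=k_neighbors)
    drop = tomek_links(Xo, yo)
    keep = np.setdiff1d(np.arange(len(Xo)), drop)
    return Xo[keep], yo[keep]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    roc_auc: float
    pr_auc: float
    threshold: float = 0.5
    model_tag: str = ""
    feature_tag: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def classification_metrics(
    y_true, y_score, threshold: float = 0.5,
    model_tag: str = "", feature_tag: str = "",
) -> MetricReport:
    """Full threshold + ranking metric panel for binary scores in [0,1].

    ROC-AUC uses the rank (Mann-Whitney) form and PR-AUC the step-wise
    precision interpolation (average precision); both are NaN for a
    single-class ``y_true``.  MCC is 0 when its denominator vanishes.
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    y_pred = (y_score >= threshold).astype(int)
    single_class = len(np.unique(y_true)) < 2
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return MetricReport(
            accuracy=accuracy_score(y_true, y_pred),
            precision=precision_score(y_true, y_pred, zero_division=0),
            recall=recall_score(y_true, y_pred, zero_division=0),
            f1=f1_score(y_true, y_pred, zero_division=0),
            mcc=float(matthews_corrcoef(y_true, y_pred)),
            roc_auc=float("nan") if single_class
            else float(roc_auc_score(y_true, y_score)),
            pr_auc=float("nan") if single_class
            else float(average_precision_score(y_true, y_score)),
            threshold=threshold,
            model_tag=model_tag,
            feature_tag=feature_tag,
        )


def best_f1_threshold(y_true, y_score):
    """Scan all distinct score cut-points for the F1 maximum.

    Ties resolve to the highest threshold.  Returns (threshold, f1).
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise BenchmarkError("both classes required")
    best_t, best_f1 = None, -1.0
    for t in np.unique(y_score):
        f1 = f1_score(y_true, (y_score >= t).astype(int), zero_division=0)
        if f1 > best_f1 or (f1 == best_f1 and (best_t is None or t > best_t)):
            best_t, best_f1 = float(t), float(f1)
    return best_t, best_f1


DEFAULT_WEIGHTS = {"f1": 0.4, "pr_auc": 0.3, "mcc": 0.2, "recall": 0.1}


@dataclass
class RankingWeights:
    w_f1: float = 0.4
    w_prauc: float = 0.3
    w_mcc: float = 0.2
    w_recall: float = 0.1

    def __post_init__(self):
        total = self.w_f1 + self.w_prauc + self.w_mcc + self.w_recall
        if abs(total - 1.0) > 1e-9:
            raise BenchmarkError(f"ranking weights sum to {total}, not 1")


def weighted_score(report: MetricReport, w: RankingWeights | None = None) -> float:
    """0.4*F1 + 0.3*PR-AUC + 0.2*MCC + 0.1*Recall."""
    w = w or RankingWeights()
    vals = (report.f1, report.pr_auc, report.mcc, report.recall)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        raise BenchmarkError("missing metric for weighted score")
    return (w.w_f1 * report.f1 + w.w_prauc * report.pr_auc
            + w.w_mcc * report.mcc + w.w_recall * report.recall)


def hierarchical_rank(reports, w: RankingWeights | None = None):
    """Sort by (recall, weighted score) descending; stable for full ties."""
    if not reports:
        raise BenchmarkError("no reports to rank")
    keyed = [(-r.recall, -weighted_score(r, w), i) for i, r in enumerate(reports)]
    order = [i for *_, i in sorted(keyed)]
    return [reports[i] for i in order]


# --------------------------------------------------------------------------
# model zoo
# --------------------------------------------------------------------------

def default_model_specs(seed: int = 0, fast: bool = False, include_boosted=True):
    """Estimator families consumed through the fit/predict_proba contract.

    Each entry: tag -> (estimator, small hyper-parameter grid).
    """
    specs = {
        "KNN": (KNeighborsClassifier(),
                {"n_neighbors": [3, 5]} if not fast else {"n_neighbors": [5]}),
        "SVM": (SVC(probability=True, class_weight="balanced",
                    random_state=seed),
                {"C": [1.0, 10.0]} if not fast else {"C": [1.0]}),
        "RF": (RandomForestClassifier(class_weight="balanced",
                                      random_state=seed, n_jobs=1),
               {"n_estimators": [200]} if not fast else {"n_estimators": [100]}),
        "GBDT": (GradientBoostingClassifier(random_state=seed),
                 {"n_estimators": [100, 200]} if not fast
                 else {"n_estimators": [100]}),
    }
    if include_boosted:
        try:
            from xgboost import XGBClassifier
            specs["XGB"] = (
                XGBClassifier(random_state=seed, n_jobs=1,
                              eval_metric="logloss"),
                {"n_estimators": [100]} if fast else {"n_estimators": [100, 200]},
            )
        except ImportError:  # pragma: no cover
            pass
        try:
            from lightgbm import LGBMClassifier
            specs["LGBM"] = (
                LGBMClassifier(random_state=seed, n_jobs=1,
                               class_weight="balanced", verbose=-1),
                {"n_estimators": [100]} if fast else {"n_estimators": [100, 200]},
            )
        except ImportError:  # pragma: no cover
            pass
    return specs


def fit_classifier(
    X_train, y_train, estimator, grid=None, seed: int = 0,
    resample: bool = True, cv: int = 5,
):
    """Grid-search fit on (optionally) SMOTE+Tomek-resampled training data."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if resample:
        X_train, y_train = smote_tomek(X_train, y_train, seed=seed)
    if grid:
        cv_eff = min(cv, int(np.bincount(y_train.astype(int)).min()))
        search = GridSearchCV(
            estimator, grid, scoring="f1",
            cv=StratifiedKFold(cv_eff, shuffle=True, random_state=seed),
            n_jobs=1,
        )
        search.fit(X_train, y_train)
        return search.best_estimator_
    est = clone(estimator)
    est.fit(X_train, y_train)
    return est


def benchmark_models(
    feature_sets: dict,
    y,
    model_specs=None,
    test_size: float = 0.2,
    seed: int = 0,
    threshold: float = 0.5,
    resample: bool = True,
    cv: int = 5,
):
    """Hold-out benchmark of every model x feature-set combination.

    ``feature_sets`` maps tag -> feature matrix (rows aligned with ``y``).
    Resampling and grid search happen strictly inside the training split.
    Returns (long-format DataFrame, reports list, fitted estimators dict).
    """
    y = np.asarray(y).astype(int)
    if model_specs is None:
        model_specs = default_model_specs(seed=seed)
    reports, fitted = [], {}
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, stratify=y, random_state=seed
    )
    for ftag, X in feature_sets.items():
        X = np.asarray(X, dtype=float)
        for mtag, (est, grid) in model_specs.items():
            model = fit_classifier(
                X[train_idx], y[train_idx], est, grid=grid, seed=seed,
                resample=resample, cv=cv,
            )
            prob = model.predict_proba(X[test_idx])[:, 1]
            rep = classification_metrics(
                y[test_idx], prob, threshold=threshold,
                model_tag=mtag, feature_tag=ftag,
            )
            reports.append(rep)
            fitted[(mtag, ftag)] = model
    ranked = hierarchical_rank(reports)
    rows = [dict(r.as_dict(), weighted_score=weighted_score(r),
                 rank=ranked.index(r) + 1) for r in reports]
    return pd.DataFrame(rows), reports, fitted


# --------------------------------------------------------------------------
# regression metrics
# --------------------------------------------------------------------------

@dataclass
class RegressionReport:
    r2: float
    mae: float
    mse: float
    q2: float | None = None
    r2_ext: float | None = None
    mae_ext: float | None = None
    mse_ext: float | None = None


def regression_metrics(
    y_true, y_pred,
    model=None, X=None, y=None, cv: int = 5, seed: int = 0,
    y_true_ext=None, y_pred_ext=None,
) -> RegressionReport:
    """R2/MAE/MSE on predictions; Q2 by internal CV when model+data given.

    Q2 is the cross-validated R2 (refit per fold), so it needs the
    estimator and the design matrix, not just a prediction vector.
    External-set metrics are computed when a disjoint (y_true_ext,
    y_pred_ext) pair is supplied.  Zero-variance ``y_true`` yields NaN R2.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 3:
        raise BenchmarkError("need at least 3 observations")
    if np.var(y_true) == 0:
        r2 = float("nan")
    else:
        r2 = r2_score(y_true, y_pred)
    rep = RegressionReport(
        r2=float(r2),
        mae=float(mean_absolute_error(y_true, y_pred)),
        mse=float(mean_squared_error(y_true, y_pred)),
    )
    if model is not None and X is not None and y is not None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
        preds = np.empty_like(y)
        for tr, te in folds.split(X):
            m = clone(model)
            m.fit(X[tr], y[tr])
            preds[te] = m.predict(X[te])
        rep.q2 = float(r2_score(y, preds))
    if y_true_ext is not None and y_pred_ext is not None:
        rep.r2_ext = float(r2_score(y_true_ext, y_pred_ext))
        rep.mae_ext = float(mean_absolute_error(y_true_ext, y_pred_ext))
        rep.mse_ext = float(mean_squared_error(y_true_ext, y_pred_ext))
    return rep
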