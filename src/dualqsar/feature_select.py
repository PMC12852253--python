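"""Three-stage feature selection for the dual-inhibitor classifier.

Stage 1 ranks features by mutual information with the class label and
keeps the top 200.  Stage 2 is either Random-Forest recursive feature
elimination down to exactly 50 features, or the Boruta shadow-feature
procedure (features must repeatedly beat the best column-shuffled copy
of the data to be confirmed).  The two stage-2 selectors are alternatives
to be compared, not chained.

All selectors are deterministic given a seed, and are meant to be fit
inside the training split only; fitting once on the full dataset is
available for comparability (``paper_mode`` in the pipeline drivers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    method: str
    selected: list[str]
    scores: dict[str, float]
    history: list[dict] = field(default_factory=list)
    tentative: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selected)


def _feature_names(X, names):
    if names is None:
        names = [f"f{j}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise SelectionError("feature_names length mismatch")
    return list(names)


def mutual_information_rank(
    X, y, k: int = 200, feature_names=None, discrete: bool = True, seed: int = 0
) -> SelectionResult:
    """Rank features by mutual information with binary ``y`` (nats).

    Binary/discrete features use the plug-in (empirical contingency)
    estimator; continuous descriptor imports use the k-NN estimator.
    Ties are broken by stable feature order.  ``k`` larger than the
    feature count returns everything.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SelectionError("y is constant; mutual information undefined")
    names = _feature_names(X, feature_names)
    mi = mutual_info_classif(
        X, y, discrete_features=discrete, random_state=seed
    )
    order = np.argsort(-mi, kind="stable")[: min(k, X.shape[1])]
    return SelectionResult(
        method="MI",
        selected=[names[j] for j in order],
        scores={names[j]: float(mi[j]) for j in range(X.shape[1])},
    )


def _default_forest(seed, n_estimators=300):
    return RandomForestClassifier(
        n_estimators=n_estimators, class_weight="balanced",
        random_state=seed, n_jobs=1,
    )


def rf_rfe(
    X, y, n_target: int = 50, step: int = 1, seed: int = 0,
    feature_names=None, estimator=None,
) -> SelectionResult:
    """Recursive feature elimination driven by Random-Forest importances.

    Repeatedly fits a forest and drops the ``step`` least-important
    features until exactly ``n_target`` remain.  ``history`` logs every
    iteration (surviving count and dropped names).
    """
    if n_target < 1:
        raise SelectionError("n_target must be >= 1")
    X = np.asarray(X)
    y = np.asarray(y)
    names = _feature_names(X, feature_names)
    if X.shape[1] < n_target:
        raise SelectionError(
            f"{X.shape[1]} features supplied but n_target={n_target}"
        )
    alive = list(range(X.shape[1]))
    history = []
    final_importance = None
    while len(alive) > n_target:
        est = estimator if estimator is not None else _default_forest(seed)
        est.fit(X[:, alive], y)
        imp = est.feature_importances_
        n_drop = min(step, len(alive) - n_target)
        drop_local = np.argsort(imp, kind="stable")[:n_drop]
        dropped = [alive[j] for j in sorted(drop_local, reverse=True)]
        for j in dropped:
            alive.remove(j)
        final_importance = dict(zip(alive, np.delete(imp, drop_local)))
        history.append({
            "n_remaining": len(alive),
            "dropped": [names[j] for j in dropped],
        })
    if final_importance is None:  # already at target size: one scoring fit
        est = estimator if estimator is not None else _default_forest(seed)
        est.fit(X[:, alive], y)
        final_importance = dict(zip(alive, est.feature_importances_))
    return SelectionResult(
        method="RF-RFE",
        selected=[names[j] for j in alive],
        scores={names[j]: float(v) for j, v in final_importance.items()},
        history=history,
    )


def boruta(
    X, y, max_iter: int = 100, alpha: float = 0.05, seed: int = 0,
    feature_names=None, n_estimators: int = 300, n_target: int | None = None,
) -> SelectionResult:
    """Boruta-style all-relevant selection against shadow features.

    Each iteration appends a column-shuffled shadow copy of ``X``, fits a
    Random Forest, and scores a "hit" for every real feature whose
    importance exceeds the maximum shadow importance.  A two-sided
    binomial test at ``alpha`` against p=0.5 confirms (more hits than
    chance) or rejects (fewer) each feature; undecided features at
    ``max_iter`` are reported tentative.  With ``n_target`` set, the
    confirmed (then tentative) features are truncated/padded by mean
    importance to a fixed-size subset for model comparability.
    """
    if max_iter < 1:
        raise SelectionError("max_iter must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SelectionError("y must contain both classes")
    names = _feature_names(X, feature_names)
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    hits = np.zeros(p, dtype=int)
    trials = 0
    status = np.zeros(p, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
    imp_sum = np.zeros(p)
    history = []
    for it in range(max_iter):
        shadow = X.copy()
        for j in range(p):
            rng.shuffle(shadow[:, j])
        Z = np.hstack([X, shadow])
        est = RandomForestClassifier(
            n_estimators=n_estimators, class_weight="balanced",
            random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1,
        )
        est.fit(Z, y)
        imp = est.feature_importances_
        real, sh = imp[:p], imp[p:]
        imp_sum += real
        thresh = sh.max()
        hits += (real > thresh).astype(int)
        trials += 1
        undecided = np.where(status == 0)[0]
        for j in undecided:
            res = stats.binomtest(int(hits[j]), trials, 0.5)
            if res.pvalue < alpha:
                status[j] = 1 if hits[j] > trials / 2 else -1
        history.append({
            "iteration": it + 1,
            "n_confirmed": int((status == 1).sum()),
            "n_rejected": int((status == -1).sum()),
        })
        if not (status == 0).any():
            break
    mean_imp = imp_sum / trials
    confirmed = [j for j in range(p) if status[j] == 1]
    tentative = [j for j in range(p) if status[j] == 0]
    confirmed.sort(key=lambda j: -mean_imp[j])
    tentative.sort(key=lambda j: -mean_imp[j])
    if n_target is None:
        selected = confirmed
    else:
        selected = (confirmed + tentative)[:n_target]
        if len(selected) < n_target:  # pad with best rejected, flagged in scores
            rest = sorted((j for j in range(p) if status[j] == -1),
                          key=lambda j: -mean_imp[j])
            selected = selected + rest[: n_target - len(selected)]
    return SelectionResult(
        method="Boruta",
        selected=[names[j] for j in selected],
        scores={names[j]: float(mean_imp[j]) for j in range(p)},
        history=history,
        tentative=[names[j] for j in tentative],
    )


def select_pipeline(
    X, y, method: str = "rf-rfe", k: int = 200, n_target: int = 50,
    seed: int = 0, feature_names=None, discrete: bool = True,
) -> SelectionResult:
    """MI top-k followed by RF-RFE or Boruta on the reduced set."""
    names = _feature_names(np.asarray(X), feature_names)
    mi = mutual_information_rank(X, y, k=k, feature_names=names,
                                 discrete=discrete, seed=seed)
    idx = [names.index(n) for n in mi.selected]
    Xr = np.asarray(X)[:, idx]
    if method.lower() in ("rf-rfe", "rfe"):
        n_eff = min(n_target, Xr.shape[1])
        res = rf_rfe(Xr, y, n_target=n_eff, seed=seed,
                     feature_names=mi.selected)
    elif method.lower() == "boruta":
        res = boruta(Xr, y, seed=seed, feature_names=mi.selected,
                     n_target=n_target)
    else:
        raise SelectionError(f"unknown method {method!r}")
    res.history.insert(0, {"mi_retained": len(mi.selected)})
    return res
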