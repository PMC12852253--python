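"""Applicability-domain analysis: leverage, h*, residuals, Williams plot.

The leverage of a query x against a training design X is the hat-matrix
diagonal h = x (X'X)^- x' (pseudo-inverse when X'X is singular); training
leverages sum to rank(X).  The warning threshold is h* = 3(p+1)/n with p
the effective descriptor count and n the training-set size.  A prediction
is in-domain when h <= h* and its standardized residual lies within +/-3
(boundaries inclusive).

High-dimensional binary fingerprints (n < p, rank-deficient) can either
be handled directly through the pseudo-inverse (``space='raw-pinv'``) or
projected onto the principal components explaining 95% of the variance,
capped at 150 components (``space='pca'``), before the hat matrix is
formed; the report carries the effective p actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA


class ADError(ValueError):
    pass


def leverage(X_train, X_query=None):
    """Hat-matrix diagonal of query rows against a training design."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise ADError("empty training matrix")
    if X_query is None:
        X_query = X_train
    X_query = np.asarray(X_query, dtype=float)
    if X_query.ndim == 1:
        X_query = X_query[None, :]
    if X_query.shape[1] != X_train.shape[1]:
        raise ADError(
            f"query width {X_query.shape[1]} != train width {X_train.shape[1]}"
        )
    G = np.linalg.pinv(X_train.T @ X_train)
    return np.einsum("ij,jk,ik->i", X_query, G, X_query)


def leverage_threshold(p: int, n: int) -> float:
    """h* = 3(p+1)/n."""
    if p < 1 or n < 1:
        raise ADError("p and n must be positive")
    return 3.0 * (p + 1) / n


def standardized_residuals(y_true, y_pred, scale: float):
    """(y_true - y_pred) / scale; ``scale`` is the training residual RMSE."""
    if scale <= 0:
        raise ADError("residual scale must be positive")
    return (np.asarray(y_true, float) - np.asarray(y_pred, float)) / scale


@dataclass
class ADReport:
    leverages: np.ndarray
    h_star: float
    std_residuals: np.ndarray | None
    in_domain: np.ndarray
    p: int
    n: int
    space: str = "raw-pinv"
    train_leverages: np.ndarray | None = None
    residual_scale: float | None = None

    def fraction_in_domain(self) -> float:
        return float(np.mean(self.in_domain))


@dataclass
class ADSpace:
    """Frozen feature space (optional PCA projection) for AD queries."""

    X_train: np.ndarray
    space: str = "raw-pinv"
    var_explained: float = 0.95
    max_components: int = 150
    _pca: PCA | None = field(default=None, repr=False)
    Z_train: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        X = np.asarray(self.X_train, dtype=float)
        if self.space == "pca":
            k = min(self.max_components, min(X.shape) - 1)
            pca = PCA(n_components=k, random_state=0).fit(X)
            cum = np.cumsum(pca.explained_variance_ratio_)
            keep = int(np.searchsorted(cum, self.var_explained) + 1)
            self._pca = PCA(n_components=min(keep, k), random_state=0).fit(X)
            self.Z_train = self._pca.transform(X)
        elif self.space == "raw-pinv":
            self.Z_train = X
        else:
            raise ADError(f"unknown AD space {self.space!r}")

    @property
    def p_effective(self) -> int:
        return self.Z_train.shape[1]

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return self._pca.transform(X) if self._pca is not None else X

    def query_leverage(self, X_query):
        return leverage(self.Z_train, self.transform(X_query))


def williams_report(
    model, X_train, y_train, X_query=None, y_query=None,
    space: str = "raw-pinv", plot_path: str | None = None,
) -> ADReport:
    """Leverage + residual AD assessment for query compounds.

    Queries lacking observed activity get leverage-only flags.  With no
    query at all the report covers the training set itself.  ``model``
    must already be fitted (its training residual RMSE sets the residual
    scale).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    ads = ADSpace(X_train, space=space)
    n, p = X_train.shape[0], ads.p_effective
    h_star = leverage_threshold(p, n)
    train_h = leverage(ads.Z_train)
    resid_train = y_train - model.predict(X_train)
    scale = float(np.sqrt(np.mean(resid_train**2)))

    if X_query is None or len(np.atleast_2d(X_query)) == 0:
        res = standardized_residuals(y_train, model.predict(X_train), scale)
        in_dom = (train_h <= h_star) & (np.abs(res) <= 3)
        report = ADReport(train_h, h_star, res, in_dom, p, n, space,
                          train_leverages=train_h, residual_scale=scale)
    else:
        X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
        h = ads.query_leverage(X_query)
        if y_query is not None:
            res = standardized_residuals(
                y_query, model.predict(X_query), scale)
            in_dom = (h <= h_star) & (np.abs(res) <= 3)
        else:
            res = None
            in_dom = h <= h_star
        report = ADReport(h, h_star, res, in_dom, p, n, space,
                          train_leverages=train_h, residual_scale=scale)

    if plot_path:
        _plot_williams(report, plot_path)
    return report


def _plot_williams(report: ADReport, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if report.train_leverages is not None and report.residual_scale:
        ax.scatter(report.train_leverages,
                   np.zeros_like(report.train_leverages), s=10, alpha=0.3,
                   label="train (leverage)")
    res = (report.std_residuals if report.std_residuals is not None
           else np.zeros_like(report.leverages))
    ax.scatter(report.leverages, res, s=14, c="crimson", marker="x",
               label="query")
    ax.axvline(report.h_star, ls="--", c="k")
    ax.axhline(3, ls="--", c="gray")
    ax.axhline(-3, ls="--", c="gray")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.set_title(f"Williams plot (h* = {report.h_star:.3f})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
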