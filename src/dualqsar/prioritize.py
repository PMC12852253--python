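"""Cross-target prediction propagation and high-confidence candidate selection.

The headline procedure: apply each target's regression model to the
*other* target's dataset (cross-target propagation), keep only
AD-compliant predictions (leverage h <= h* against the predicting
model's training set), score every compound with the dual-inhibitor
classifier, and select candidates that

  (i)  have classifier probability >= ``prob_min`` (default 0.999), and
  (ii) have predicted pIC50 in the top ``top_frac`` (default 5%) of each
       regression model's output distribution for both targets, and
  (iii) are inside the applicability domain of both models.

Quantiles are inclusive linear-interpolation quantiles; records exactly
at the cut are selected.  Output is sorted by mean predicted pIC50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ad import ADSpace, leverage_threshold


class PrioritizeError(ValueError):
    pass


@dataclass
class CrossTargetPredictions:
    compound_ids: list[str]
    predictions: np.ndarray
    leverages: np.ndarray
    h_star: float

    @property
    def ad_ok(self) -> np.ndarray:
        return self.leverages <= self.h_star


def cross_target_predict(model, X_query, compound_ids, ad_space: ADSpace):
    """Predict with ``model`` and flag AD compliance against its train set.

    ``ad_space`` must be built on the model's training design in the same
    feature space as ``X_query``.
    """
    X_query = np.asarray(X_query, dtype=float)
    if len(X_query) == 0:
        return CrossTargetPredictions(
            [], np.empty(0), np.empty(0),
            leverage_threshold(ad_space.p_effective, len(ad_space.X_train)))
    if X_query.shape[1] != np.asarray(ad_space.X_train).shape[1]:
        raise PrioritizeError("feature-space mismatch with AD training set")
    preds = model.predict(X_query)
    h = ad_space.query_leverage(X_query)
    h_star = leverage_threshold(ad_space.p_effective, len(ad_space.X_train))
    return CrossTargetPredictions(list(compound_ids), preds, h, h_star)


def select_candidates(
    records: pd.DataFrame,
    prob_min: float = 0.999,
    top_frac: float = 0.05,
    ache_population=None,
    bace_population=None,
) -> pd.DataFrame:
    """Apply the probability / top-percentile / AD selection rule.

    ``records`` needs columns: compound_id, prob_dual, pred_pic50_ache,
    pred_pic50_bace, ad_ok.  The percentile cut-offs are computed per
    target over ``*_population`` (the full regression output
    distribution) when given, else over the records themselves.
    """
    required = {"compound_id", "prob_dual", "pred_pic50_ache",
                "pred_pic50_bace", "ad_ok"}
    missing = required - set(records.columns)
    if missing:
        raise PrioritizeError(f"missing columns: {sorted(missing)}")
    if len(records) < 20:
        import warnings
        warnings.warn("fewer than 20 records; percentile cut-offs unstable")
    q = 1.0 - top_frac
    pop_a = (np.asarray(ache_population, float) if ache_population is not None
             else records["pred_pic50_ache"].to_numpy())
    pop_b = (np.asarray(bace_population, float) if bace_population is not None
             else records["pred_pic50_bace"].to_numpy())
    cut_a = float(np.quantile(pop_a, q)) if len(pop_a) else np.inf
    cut_b = float(np.quantile(pop_b, q)) if len(pop_b) else np.inf
    out = records.copy()
    out["cut_ache"] = cut_a
    out["cut_bace"] = cut_b
    out["selected"] = (
        (out["prob_dual"] >= prob_min)
        & (out["pred_pic50_ache"] >= cut_a)
        & (out["pred_pic50_bace"] >= cut_b)
        & out["ad_ok"].astype(bool)
    )
    out["mean_pred_pic50"] = (out["pred_pic50_ache"]
                              + out["pred_pic50_bace"]) / 2.0
    return out.sort_values(
        "mean_pred_pic50", ascending=False, kind="stable"
    ).reset_index(drop=True)


def build_candidate_records(
    compound_ids,
    prob_dual,
    pred_ache,
    pred_bace,
    h_ache,
    h_bace,
    h_star_ache: float,
    h_star_bace: float,
    source_dataset: str = "",
) -> pd.DataFrame:
    """Assemble the candidate table from per-compound predictions."""
    df = pd.DataFrame({
        "compound_id": list(compound_ids),
        "source_dataset": source_dataset,
        "prob_dual": np.asarray(prob_dual, float),
        "pred_pic50_ache": np.asarray(pred_ache, float),
        "pred_pic50_bace": np.asarray(pred_bace, float),
        "h_ache": np.asarray(h_ache, float),
        "h_bace": np.asarray(h_bace, float),
    })
    df["ad_ok"] = (df["h_ache"] <= h_star_ache) & (df["h_bace"] <= h_star_bace)
    return df
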