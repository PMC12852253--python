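"""Additive attribution reporting over fingerprint bits.

Tree ensembles are explained with exact decision-path (Saabas-style)
attributions: walking each tree from root to leaf, the change in node
value at every split is credited to the split feature, so for every
compound

    base_value + sum(contributions) == model output        (exactly)

where the model output is the predicted probability of the positive
class (random forests), the raw margin (gradient boosting classifiers)
or the predicted value (regressors).  Linear models decompose exactly as
coef * (x - background mean).  Shapley-value estimation is deliberately
not implemented here; the path attribution is a different, exactly
additive credit scheme with the same reporting surface.

MACCS bits map to their predefined SMARTS keys; folded ECFP bits map to
the atom environments (central atom + radius <= 3 neighbourhood) that
set them -- all environments are returned on a folding collision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


class ExplainError(ValueError):
    pass


# --------------------------------------------------------------------------
# exact additive attributions
# --------------------------------------------------------------------------

def _tree_node_values(tree, class_index: int | None):
    """Per-node scalar values for one sklearn tree."""
    v = tree.value  # (n_nodes, n_outputs, n_classes_or_1)
    if class_index is None:
        return v[:, 0, 0]
    row = v[:, 0, :]
    totals = row.sum(axis=1, keepdims=True)
    probs = np.divide(row, totals, out=np.zeros_like(row), where=totals > 0)
    return probs[:, class_index]


def _single_tree_contribs(tree, X, class_index=None, scale: float = 1.0):
    """Decision-path contributions for one fitted sklearn tree."""
    values = _tree_node_values(tree, class_index) * scale
    left, right, feat = tree.children_left, tree.children_right, tree.feature
    n, p = X.shape
    contribs = np.zeros((n, p))
    for i in range(n):
        node = 0
        while left[node] != -1:
            f = feat[node]
            child = (left[node] if X[i, f] <= tree.threshold[node]
                     else right[node])
            contribs[i, f] += values[child] - values[node]
            node = child
    return contribs


def tree_attributions(model, X):
    """Exact additive (contribs, base, predictions) for a tree model.

    Supported: decision trees, random forests (probability space for
    classifiers), gradient boosting (raw margin for classifiers).
    """
    X = np.asarray(X, dtype=float)
    if isinstance(model, (DecisionTreeRegressor,)):
        contribs = _single_tree_contribs(model.tree_, X)
        predicted = model.predict(X)
    elif isinstance(model, DecisionTreeClassifier):
        ci = list(model.classes_).index(model.classes_[-1])
        contribs = _single_tree_contribs(model.tree_, X, class_index=ci)
        predicted = model.predict_proba(X)[:, ci]
    elif isinstance(model, RandomForestRegressor):
        contribs = np.mean(
            [_single_tree_contribs(t.tree_, X) for t in model.estimators_],
            axis=0)
        predicted = model.predict(X)
    elif isinstance(model, RandomForestClassifier):
        ci = list(model.classes_).index(model.classes_[-1])
        contribs = np.mean(
            [_single_tree_contribs(t.tree_, X, class_index=ci)
             for t in model.estimators_], axis=0)
        predicted = model.predict_proba(X)[:, ci]
    elif isinstance(model, (GradientBoostingRegressor,
                            GradientBoostingClassifier)):
        lr = model.learning_rate
        contribs = np.zeros_like(X, dtype=float)
        for stage in model.estimators_:
            for t in np.ravel(stage):
                contribs += _single_tree_contribs(t.tree_, X, scale=lr)
        if isinstance(model, GradientBoostingClassifier):
            predicted = model.decision_function(X)
        else:
            predicted = model.predict(X)
    else:
        raise ExplainError(
            f"unsupported model type {type(model).__name__}; tree and "
            "linear models are explainable")
    base_vec = predicted - contribs.sum(axis=1)
    if np.ptp(base_vec) > 1e-6:
        raise ExplainError("path walk inconsistent with model predictions")
    return contribs, float(base_vec.mean()), predicted


def linear_attributions(model, X, background=None):
    """Exact additive contributions coef * (x - background mean)."""
    X = np.asarray(X, dtype=float)
    coef = np.ravel(model.coef_)
    bg = (np.zeros(X.shape[1]) if background is None
          else np.asarray(background, float).mean(axis=0))
    contribs = (X - bg) * coef
    base = float(model.intercept_ + coef @ bg)
    predicted = model.predict(X)
    return contribs, base, predicted


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

@dataclass
class AttributionReport:
    contributions: np.ndarray  # compounds x features
    base_value: float
    feature_names: list[str]
    ranking: list[str] = field(default_factory=list)
    direction: dict[str, int] = field(default_factory=dict)
    mean_abs: dict[str, float] = field(default_factory=dict)


def attribution_summary(
    contribs, base: float, feature_names=None, top_k: int = 15,
    feature_values=None,
) -> AttributionReport:
    """Rank features by mean |contribution|; record direction of effect.

    Direction is the sign of the mean contribution; when the feature
    matrix is supplied via ``feature_values`` the mean is taken over
    rows with an above-average feature value (for binary fingerprints,
    the bit carriers), which is the informative convention: over *all*
    rows the path contributions of a split feature average to ~0.
    Features whose contributions are identically zero are left out of
    the ranking.
    """
    contribs = np.asarray(contribs, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(contribs.shape[1])]
    if len(feature_names) != contribs.shape[1]:
        raise ExplainError("feature_names length mismatch")
    mean_abs = np.mean(np.abs(contribs), axis=0)
    if feature_values is not None:
        X = np.asarray(feature_values, dtype=float)
        if X.shape != contribs.shape:
            raise ExplainError("feature_values shape mismatch")
        high = X > X.mean(axis=0, keepdims=True)
        counts = high.sum(axis=0)
        sums = np.where(high, contribs, 0.0).sum(axis=0)
        mean_signed = np.divide(sums, counts,
                                out=np.zeros(contribs.shape[1]),
                                where=counts > 0)
    else:
        mean_signed = np.mean(contribs, axis=0)
    order = [j for j in np.argsort(-mean_abs, kind="stable") if mean_abs[j] > 0]
    ranking = [feature_names[j] for j in order[:top_k]]
    return AttributionReport(
        contributions=contribs,
        base_value=float(base),
        feature_names=list(feature_names),
        ranking=ranking,
        direction={feature_names[j]: int(np.sign(mean_signed[j]))
                   for j in order},
        mean_abs={feature_names[j]: float(mean_abs[j]) for j in order},
    )


def additivity_check(contribs, base, predictions, tol: float = 1e-6):
    """Per-compound flag: base + sum(contributions) == prediction (tol)."""
    contribs = np.asarray(contribs, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if contribs.shape[0] != len(predictions):
        raise ExplainError("shape mismatch")
    return np.abs(base + contribs.sum(axis=1) - predictions) <= tol


def attribution_bar_plot(report: AttributionReport, path: str,
                         top_k: int = 15) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = report.ranking[:top_k][::-1]
    vals = [report.mean_abs[n] for n in names]
    colors = ["tab:blue" if report.direction[n] >= 0 else "tab:orange"
              for n in names]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(names) + 1.5))
    ax.barh(names, vals, color=colors)
    ax.set_xlabel("mean |contribution|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# bit -> substructure
# --------------------------------------------------------------------------

@dataclass
class FragmentRecord:
    bit_index: int
    kind: str
    environments: list[dict]  # per setting environment
    smarts: str | None = None


def bit_to_fragment(smiles: str, bit_index: int, kind: str = "ECFP6"
                    ) -> FragmentRecord:
    """Map a fingerprint bit to the substructure(s) that set it.

    ECFP6 bits return every atom environment (central atom index, radius,
    member atoms, environment SMILES) hashing to the bit in this molecule
    (folding collisions yield several).  MACCS bits return the predefined
    SMARTS key plus its matches.  A bit the molecule does not set is an
    error.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ExplainError(f"unparsable SMILES {smiles!r}")
    kind = kind.upper()
    if kind == "ECFP6":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        gen.GetFingerprint(mol, additionalOutput=ao)
        info = ao.GetBitInfoMap()
        if bit_index not in info:
            raise ExplainError(f"bit {bit_index} not set by this molecule")
        envs = []
        for atom_idx, radius in info[bit_index]:
            if radius > 0:
                bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
                amap: dict[int, int] = {}
                sub = Chem.PathToSubmol(mol, bonds, atomMap=amap)
                env_smiles = Chem.MolToSmiles(sub)
                atoms = sorted(amap)
            else:
                env_smiles = mol.GetAtomWithIdx(atom_idx).GetSymbol()
                atoms = [atom_idx]
            envs.append({
                "center_atom": int(atom_idx),
                "radius": int(radius),
                "atoms": [int(a) for a in atoms],
                "smiles": env_smiles,
                "aromatic": bool(
                    mol.GetAtomWithIdx(atom_idx).GetIsAromatic()),
            })
        return FragmentRecord(bit_index=bit_index, kind=kind,
                              environments=envs)
    if kind == "MACCS":
        smarts, _count = MACCSkeys.smartsPatts.get(bit_index, (None, 0))
        if smarts in (None, "?"):
            raise ExplainError(f"MACCS key {bit_index} has no SMARTS pattern")
        patt = Chem.MolFromSmarts(smarts)
        matches = mol.GetSubstructMatches(patt) if patt is not None else ()
        if not matches:
            raise ExplainError(f"bit {bit_index} not set by this molecule")
        envs = [{"atoms": [int(a) for a in m], "smiles": smarts}
                for m in matches]
        return FragmentRecord(bit_index=bit_index, kind=kind,
                              environments=envs, smarts=smarts)
    raise ExplainError(f"unsupported fingerprint kind {kind!r}")
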