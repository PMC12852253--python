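"""Bioactivity curation and dual-inhibitor dataset construction.

Implements the standard ChEMBL-style cleanup chain for IC50 tables:
removal of records lacking a numeric IC50 or carrying ambiguous
stereochemistry, removal of salts/mixtures/metal-containing compounds,
duplicate resolution (keep the most potent record per compound+target),
and a greedy Tanimoto redundancy filter.  The curated AChE and BACE1
tables are then cross-matched into a dual-inhibitor classification
dataset: class 1 iff pIC50 > 6.0 (IC50 < 1 uM) for both targets.

All IC50 values are stored internally in mol/L; pIC50 = -log10(IC50 [M]).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .featurize import FingerprintSet, tanimoto

RDLogger.DisableLog("rdApp.*")

#: elements allowed in the "organic subset"; anything else counts as a metal
#: (or metalloid) and triggers removal.
ORGANIC_SUBSET = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

DEFAULT_PIC50_THRESHOLD = 6.0
DEFAULT_TANIMOTO_THRESHOLD = 0.80


class CurationError(ValueError):
    """Raised on contract violations inside the curation pipeline."""


def to_pic50(ic50):
    """pIC50 = -log10(IC50 in mol/L).

    Accepts a positive scalar or array-like; raises ``ValueError`` for
    non-positive or missing values.

    >>> to_pic50(1e-6)
    6.0
    """
    arr = np.asarray(ic50, dtype=float)
    if arr.size == 0:
        raise ValueError("empty IC50 input")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("IC50 must be positive and finite (mol/L)")
    out = -np.log10(arr)
    return float(out) if np.isscalar(ic50) or arr.ndim == 0 else out


@dataclass
class CompoundRecord:
    """One compound-target activity measurement and its curation status."""

    compound_id: str
    smiles: str
    target_id: str
    ic50: float | None = None  # mol/L
    pic50: float | None = None
    status: str = "kept"
    artifact: str | None = None  # hidden injection flag, never serialized

    def __post_init__(self):
        if self.pic50 is None and self.ic50 is not None and self.ic50 > 0:
            self.pic50 = to_pic50(self.ic50)

    @property
    def kept(self) -> bool:
        return self.status == "kept"

    def remove(self, reason: str) -> None:
        # a record carries exactly one primary removal reason
        if self.status == "kept":
            self.status = f"removed:{reason}"


@dataclass
class BioactivityTable:
    """Ordered record list plus an audit trail of per-step survivor counts."""

    records: list[CompoundRecord] = field(default_factory=list)
    audit: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def kept_records(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.kept]

    def n_kept(self) -> int:
        return sum(1 for r in self.records if r.kept)

    def log_step(self, step: str) -> None:
        n = self.n_kept()
        last = next(reversed(self.audit.values()), None)
        if last is not None and n > last:
            raise CurationError(
                f"audit count increased at step {step!r}: {last} -> {n}"
            )
        self.audit[step] = n

    # ------------------------------------------------------------------ I/O
    @classmethod
    def read_csv(cls, path_or_buf, target_id: str | None = None) -> "BioactivityTable":
        """Read a delimited bioactivity table.

        Expected header: compound_id, smiles, target_id, standard_value_nM.
        ``standard_value_nM`` is the IC50 in nM (ChEMBL convention); it is
        converted to mol/L on ingest.
        """
        df = pd.read_csv(path_or_buf, dtype={"compound_id": str, "smiles": str})
        required = {"compound_id", "smiles", "standard_value_nM"}
        missing = required - set(df.columns)
        if missing:
            raise CurationError(f"missing columns: {sorted(missing)}")
        records = []
        for row in df.itertuples(index=False):
            raw = getattr(row, "standard_value_nM")
            ic50 = None
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                try:
                    val = float(raw)
                    ic50 = val * 1e-9 if val > 0 else None
                except (TypeError, ValueError):
                    ic50 = None
            records.append(
                CompoundRecord(
                    compound_id=str(row.compound_id),
                    smiles="" if pd.isna(row.smiles) else str(row.smiles),
                    target_id=target_id
                    or str(getattr(row, "target_id", "NA")),
                    ic50=ic50,
                )
            )
        table = cls(records=records)
        table.log_step("raw")
        return table

    def to_csv(self, path_or_buf=None, kept_only: bool = True):
        rows = self.kept_records() if kept_only else self.records
        df = pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in rows],
                "smiles": [r.smiles for r in rows],
                "target_id": [r.target_id for r in rows],
                "standard_value_nM": [
                    "" if r.ic50 is None else r.ic50 * 1e9 for r in rows
                ],
            }
        )
        return df.to_csv(path_or_buf, index=False)

    def write_audit(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.audit, fh, indent=2)


# --------------------------------------------------------------------------
# curation steps
# --------------------------------------------------------------------------

def _has_metal(mol) -> bool:
    return any(a.GetSymbol() not in ORGANIC_SUBSET for a in mol.GetAtoms())


def _ambiguous_stereo(mol) -> bool:
    """True when the molecule has a stereocenter left unspecified."""
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return any(tag == "?" for _, tag in centers)


def filter_invalid(
    table: BioactivityTable,
    metal_elements: frozenset[str] | None = None,
    check_stereo: bool = True,
) -> BioactivityTable:
    """Apply the structural/record validity rules in two audited passes.

    Pass 1 removes records lacking a numeric IC50 and (optionally) those
    with ambiguous stereochemistry; pass 2 removes salts/mixtures (more
    than one disconnected SMILES component) and metal-containing
    compounds.  Unparsable SMILES become ``removed:parse_error``.
    """
    # pass 1: missing IC50 / parse errors / ambiguous stereo
    for rec in table.kept_records():
        if rec.ic50 is None:
            rec.remove("missing_ic50")
            continue
        mol = Chem.MolFromSmiles(rec.smiles) if rec.smiles else None
        if mol is None:
            rec.remove("parse_error")
            continue
        if check_stereo and _ambiguous_stereo(mol):
            rec.remove("ambiguous_stereo")
    table.log_step("missing_ic50_stereo")

    # pass 2: salts/mixtures/metals
    metal_set = metal_elements  # explicit list overrides the organic-subset rule
    for rec in table.kept_records():
        if rec.smiles.count(".") >= 1:
            rec.remove("salt_or_mixture")
            continue
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:  # pragma: no cover - caught in pass 1
            rec.remove("parse_error")
            continue
        if metal_set is not None:
            is_metal = any(a.GetSymbol() in metal_set for a in mol.GetAtoms())
        else:
            is_metal = _has_metal(mol)
        if is_metal:
            rec.remove("metal")
    table.log_step("salts_mixtures_metals")
    return table


def resolve_duplicates(table: BioactivityTable) -> BioactivityTable:
    """Keep only the maximum-pIC50 record per (compound_id, target).

    Exact pIC50 ties keep the first record in stable input order.
    """
    best: dict[tuple[str, str], CompoundRecord] = {}
    for rec in table.kept_records():
        key = (rec.compound_id, rec.target_id)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
        elif rec.pic50 is not None and (cur.pic50 is None or rec.pic50 > cur.pic50):
            cur.remove("duplicate")
            best[key] = rec
        else:
            rec.remove("duplicate")
    table.log_step("duplicates")
    return table


def redundancy_filter(
    table: BioactivityTable,
    fps: FingerprintSet,
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
) -> BioactivityTable:
    """Greedy leader redundancy filter in stable input order.

    A kept record is removed when its Tanimoto similarity to any
    already-retained record is >= ``threshold``; consequently no retained
    pair has similarity >= threshold.  ``fps`` rows are matched to records
    by compound_id.
    """
    index = {cid: i for i, cid in enumerate(fps.compound_ids)}
    retained_rows: list[np.ndarray] = []
    for rec in table.kept_records():
        row_idx = index.get(rec.compound_id)
        if row_idx is None:
            raise CurationError(
                f"no fingerprint for record {rec.compound_id!r}"
            )
        row = fps.matrix[row_idx]
        if any(tanimoto(row, prev) >= threshold for prev in retained_rows):
            rec.remove("redundant")
        else:
            retained_rows.append(row)
    table.log_step("tanimoto_redundancy")
    return table


def curate(
    table: BioactivityTable,
    fps_fn,
    tanimoto_threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
    check_stereo: bool = True,
) -> BioactivityTable:
    """Full curation chain: validity -> duplicates -> Tanimoto redundancy.

    ``fps_fn(smiles_list, compound_ids)`` must return a FingerprintSet for
    the records surviving the structural filters (fingerprints can only be
    computed for parsable, single-component molecules).
    """
    filter_invalid(table, check_stereo=check_stereo)
    resolve_duplicates(table)
    kept = table.kept_records()
    if kept:
        fps = fps_fn([r.smiles for r in kept], [r.compound_id for r in kept])
        redundancy_filter(table, fps, threshold=tanimoto_threshold)
    else:
        table.log_step("tanimoto_redundancy")
    table.log_step("final")
    return table


# --------------------------------------------------------------------------
# dual dataset
# --------------------------------------------------------------------------

@dataclass
class DualDataset:
    """Compounds with measured pIC50 for both targets and a dual label.

    label = 1 iff pIC50 > threshold for *both* targets (strict).
    """

    entries: pd.DataFrame  # compound_id, pic50_ache, pic50_bace, label
    threshold: float = DEFAULT_PIC50_THRESHOLD

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> np.ndarray:
        return self.entries["label"].to_numpy()

    @property
    def compound_ids(self) -> list[str]:
        return self.entries["compound_id"].tolist()

    def class_counts(self) -> tuple[int, int]:
        y = self.labels
        return int((y == 0).sum()), int((y == 1).sum())

    def imbalance_ratio(self) -> float:
        n0, n1 = self.class_counts()
        return n0 / n1 if n1 else math.inf


def build_dual_dataset(
    ache: BioactivityTable,
    bace: BioactivityTable,
    threshold: float = DEFAULT_PIC50_THRESHOLD,
) -> DualDataset:
    """Cross-match curated tables on compound_id and assign dual labels."""
    a = {r.compound_id: r for r in ache.kept_records()}
    b = {r.compound_id: r for r in bace.kept_records()}
    common = [cid for cid in a if cid in b]
    if not common:
        warnings.warn("empty intersection between AChE and BACE1 tables")
    rows = []
    for cid in common:
        pa, pb = a[cid].pic50, b[cid].pic50
        label = int(pa is not None and pb is not None
                    and pa > threshold and pb > threshold)
        rows.append((cid, pa, pb, label))
    df = pd.DataFrame(rows, columns=["compound_id", "pic50_ache", "pic50_bace", "label"])
    return DualDataset(entries=df, threshold=threshold)


# --------------------------------------------------------------------------
# descriptive statistics
# --------------------------------------------------------------------------

@dataclass
class DiversityStats:
    n: int
    n_pairs: int
    mean_sim: float
    median_sim: float
    frac_above: float
    cutoff: float


def diversity_stats(fps: FingerprintSet, cutoff: float = 0.7) -> DiversityStats:
    """Pairwise Tanimoto diversity over all unordered fingerprint pairs."""
    n = fps.matrix.shape[0]
    if n < 2:
        raise CurationError("diversity statistics need at least 2 compounds")
    X = fps.matrix.astype(np.float64)
    inter = X @ X.T
    counts = X.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    iu = np.triu_indices(n, k=1)
    u = union[iu]
    sims = np.where(u == 0, 1.0, inter[iu] / np.where(u == 0, 1.0, u))
    return DiversityStats(
        n=n,
        n_pairs=len(sims),
        mean_sim=float(np.mean(sims)),
        median_sim=float(np.median(sims)),
        frac_above=float(np.mean(sims > cutoff)),
        cutoff=cutoff,
    )


def potency_consistency(dual: DualDataset, delta: float = 0.5):
    """Count class-1 entries whose |pIC50(AChE) - pIC50(BACE1)| < delta.

    Returns (count, proportion over class-1 entries); proportion is NaN
    when there are no class-1 entries.
    """
    if len(dual) == 0:
        raise CurationError("empty dual dataset")
    pos = dual.entries[dual.entries["label"] == 1]
    if len(pos) == 0:
        return 0, float("nan")
    diffs = (pos["pic50_ache"] - pos["pic50_bace"]).abs()
    count = int((diffs < delta).sum())
    return count, count / len(pos)
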