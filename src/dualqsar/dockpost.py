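"""Docking post-analysis: dG -> Ki conversion, correlations, redocking RMSD.

The inhibition constant implied by a docking binding free energy dG
(kcal/mol) is Ki = exp(dG / RT) with R = 1.98720e-3 kcal/(mol K) and
T = 298.15 K (RT = 0.59248 kcal/mol, the AutoDock convention).
Docking-activity consistency is a Pearson correlation between binding
energies and experimental pIC50 values; redocking validation passes
when the pose RMSD against the crystallographic ligand is below 2.0 A
(strict).  RMSD is computed without superposition: redocked poses share
the receptor frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

R_KCAL = 1.98720e-3  # kcal / (mol K)
T_STANDARD = 298.15  # K
RT_STANDARD = R_KCAL * T_STANDARD  # 0.59248 kcal/mol

REDOCK_RMSD_CUTOFF = 2.0  # Angstrom


class DockingError(ValueError):
    pass


def ki_from_dg(dg: float, temperature: float = T_STANDARD) -> float:
    """Ki (mol/L) implied by a binding free energy in kcal/mol."""
    dg = float(dg)
    if not np.isfinite(dg):
        raise DockingError("dG must be finite")
    return float(np.exp(dg / (R_KCAL * temperature)))


def dg_from_ki(ki: float, temperature: float = T_STANDARD) -> float:
    """Inverse of :func:`ki_from_dg` (dG = RT ln Ki)."""
    if ki <= 0:
        raise DockingError("Ki must be positive")
    return float(R_KCAL * temperature * np.log(ki))


def format_ki(ki_molar: float) -> str:
    """Human-readable Ki with an auto-selected unit (M/mM/uM/nM/pM)."""
    for unit, scale in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6),
                        ("nM", 1e-9), ("pM", 1e-12)):
        if ki_molar >= scale:
            return f"{ki_molar / scale:.2f} {unit}"
    return f"{ki_molar / 1e-12:.2g} pM"


KI_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass
class DockingRecord:
    ligand_id: str
    target: str  # AChE | BACE1
    dg: float  # kcal/mol, negative = favorable
    ki: float  # mol/L
    hbond_residues: list[str] = field(default_factory=list)

    @classmethod
    def from_dg(cls, ligand_id, target, dg, hbond_residues=None):
        return cls(ligand_id=ligand_id, target=target, dg=dg,
                   ki=ki_from_dg(dg),
                   hbond_residues=list(hbond_residues or []))


@dataclass
class CorrelationReport:
    r: float
    r2: float
    p_value: float
    n: int


def docking_activity_correlation(dg_values, pic50_values) -> CorrelationReport:
    """Pearson correlation between docking energies and measured pIC50.

    Two-sided t-test p-value with n-2 degrees of freedom.  Zero variance
    in either vector yields NaN r (undefined).
    """
    dg = np.asarray(dg_values, dtype=float)
    p = np.asarray(pic50_values, dtype=float)
    if len(dg) != len(p):
        raise DockingError("paired vectors must have equal length")
    if len(dg) < 3:
        raise DockingError("need n >= 3 pairs")
    if np.var(dg) == 0 or np.var(p) == 0:
        return CorrelationReport(float("nan"), float("nan"), float("nan"),
                                 len(dg))
    r, pval = stats.pearsonr(dg, p)
    return CorrelationReport(r=float(r), r2=float(r * r),
                             p_value=float(pval), n=len(dg))


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation in a shared frame (no superposition)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise DockingError(f"atom-count mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def validate_redock(rmsd_value: float,
                    cutoff: float = REDOCK_RMSD_CUTOFF) -> bool:
    """Redocking acceptance: RMSD strictly below the cutoff."""
    if rmsd_value < 0:
        raise DockingError("RMSD cannot be negative")
    return rmsd_value < cutoff


# --------------------------------------------------------------------------
# bundled study tables
# --------------------------------------------------------------------------

def _load_data(name: str) -> pd.DataFrame:
    with resources.files("dualqsar.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_docking_table() -> pd.DataFrame:
    """Bundled docking result table (per-ligand dG/Ki for both targets)."""
    df = _load_data("docking_table.csv")
    for t in ("ache", "bace1"):
        df[f"ki_{t}_molar"] = [
            v * KI_UNIT_SCALE[u]
            for v, u in zip(df[f"ki_{t}_printed"], df[f"ki_{t}_unit"])
        ]
    return df


def load_candidate_table() -> pd.DataFrame:
    """Bundled high-confidence candidate table (experimental pIC50s)."""
    return _load_data("candidate_table.csv")


def docking_records(target: str = "AChE") -> list[DockingRecord]:
    df = load_docking_table()
    key = "ache" if target.lower() in ("ache", "achE".lower()) else "bace1"
    return [
        DockingRecord.from_dg(
            row.ligand_id, target, getattr(row, f"dg_{key}_kcal_mol"),
            str(getattr(row, f"hbonds_{key}")).split(";"))
        for row in df.itertuples(index=False)
    ]


def study_correlations() -> dict[str, CorrelationReport]:
    """Docking-activity correlation per target for the bundled candidates.

    Pairs each candidate's experimental pIC50 (on the dataset it came
    from) with its docking energy against that same target.
    """
    cands = load_candidate_table()
    dock = load_docking_table().set_index("ligand_id")
    out = {}
    for target, key in (("AChE", "ache"), ("BACE1", "bace1")):
        sub = cands[cands["source_dataset"] == target]
        dg = dock.loc[sub["ligand_id"], f"dg_{key}_kcal_mol"].to_numpy()
        out[target] = docking_activity_correlation(dg, sub["exp_pic50"])
    return out
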