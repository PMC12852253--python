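"""Fingerprint featurization and simple drug-likeness properties.

Fingerprints are computed with RDKit and exposed as dense binary
matrices with exact bit-length contracts:

==========  =====  ===========================================
kind        bits   backend
==========  =====  ===========================================
ECFP6       2048   Morgan generator, radius 3 (diameter 6)
MACCS       166    MACCS keys (RDKit bit 0 is unused, dropped)
PATH1024    1024   RDKit path-based topological fingerprint
PUBCHEM881  881    not available in RDKit; raises
COMBINED    2214   MACCS (first) + ECFP6, column concatenation
==========  =====  ===========================================

ECFP6 environment metadata (bit -> (atom, radius) per molecule) is
retained when requested so that attribution results can be mapped back
to substructures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

BIT_WIDTHS = {
    "ECFP6": 2048,
    "MACCS": 166,
    "PATH1024": 1024,
    "PUBCHEM881": 881,
    "COMBINED": 2214,
}


class FeatureNotAvailable(RuntimeError):
    """A requested fingerprint family has no backend implementation."""


@dataclass
class FingerprintSet:
    kind: str
    matrix: np.ndarray  # (compounds, bits) uint8 in {0,1}
    bit_names: list[str]
    compound_ids: list[str]
    #: per-compound ECFP environment map: bit -> tuple of (atom_idx, radius)
    bit_info: list[dict] | None = None

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValueError("fingerprint matrix must be 2-D")
        if self.matrix.shape[1] != len(self.bit_names):
            raise ValueError("bit_names length does not match matrix width")
        if self.matrix.shape[0] != len(self.compound_ids):
            raise ValueError("compound_ids length does not match matrix rows")

    @property
    def n_bits(self) -> int:
        return self.matrix.shape[1]

    def row(self, compound_id: str) -> np.ndarray:
        return self.matrix[self.compound_ids.index(compound_id)]


def _parse_all(smiles_list):
    mols, bad = [], []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            bad.append(smi)
        mols.append(mol)
    if bad:
        raise ValueError(f"unparsable SMILES: {bad}")
    return mols


def compute_fingerprints(
    smiles_list,
    kind: str = "ECFP6",
    compound_ids=None,
    keep_bit_info: bool = False,
) -> FingerprintSet:
    """Compute a binary fingerprint matrix for a list of SMILES."""
    kind = kind.upper()
    if kind not in BIT_WIDTHS:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    if kind == "PUBCHEM881":
        raise FeatureNotAvailable(
            "PubChem/CACTVS 881-bit keys have no RDKit implementation; "
            "import an externally computed matrix instead"
        )
    if compound_ids is None:
        compound_ids = [f"CPD{i:06d}" for i in range(len(smiles_list))]
    compound_ids = list(compound_ids)
    mols = _parse_all(smiles_list)

    if kind == "COMBINED":
        maccs = compute_fingerprints(smiles_list, "MACCS", compound_ids)
        ecfp = compute_fingerprints(
            smiles_list, "ECFP6", compound_ids, keep_bit_info=keep_bit_info
        )
        return combine_features(maccs, ecfp)

    n = len(mols)
    bit_info: list[dict] | None = None
    if kind == "ECFP6":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
        mat = np.zeros((n, 2048), dtype=np.uint8)
        if keep_bit_info:
            bit_info = []
        for i, mol in enumerate(mols):
            if keep_bit_info:
                ao = rdFingerprintGenerator.AdditionalOutput()
                ao.AllocateBitInfoMap()
                fp = gen.GetFingerprint(mol, additionalOutput=ao)
                bit_info.append(dict(ao.GetBitInfoMap()))
            else:
                fp = gen.GetFingerprint(mol)
            mat[i, list(fp.GetOnBits())] = 1
        names = [f"ECFP_{i}" for i in range(2048)]
    elif kind == "MACCS":
        mat = np.zeros((n, 166), dtype=np.uint8)
        for i, mol in enumerate(mols):
            fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
            on = [b - 1 for b in fp.GetOnBits() if b >= 1]
            mat[i, on] = 1
        names = [f"MACCS_{i}" for i in range(1, 167)]
    elif kind == "PATH1024":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=1024)
        mat = np.zeros((n, 1024), dtype=np.uint8)
        for i, mol in enumerate(mols):
            fp = gen.GetFingerprint(mol)
            mat[i, list(fp.GetOnBits())] = 1
        names = [f"PATH_{i}" for i in range(1024)]
    else:  # pragma: no cover
        raise AssertionError(kind)

    return FingerprintSet(
        kind=kind, matrix=mat, bit_names=names,
        compound_ids=compound_ids, bit_info=bit_info,
    )


def combine_features(maccs: FingerprintSet, ecfp: FingerprintSet) -> FingerprintSet:
    """Column-wise concatenation, MACCS block first (width 166+2048=2214)."""
    if maccs.compound_ids != ecfp.compound_ids:
        raise ValueError("compound lists differ between fingerprint sets")
    mat = np.concatenate([maccs.matrix, ecfp.matrix], axis=1)
    names = list(maccs.bit_names) + list(ecfp.bit_names)
    return FingerprintSet(
        kind="COMBINED", matrix=mat, bit_names=names,
        compound_ids=list(maccs.compound_ids), bit_info=ecfp.bit_info,
    )


def split_combined(fps: FingerprintSet) -> tuple[FingerprintSet, FingerprintSet]:
    """Inverse of :func:`combine_features`."""
    if fps.kind != "COMBINED":
        raise ValueError("not a COMBINED fingerprint set")
    w = BIT_WIDTHS["MACCS"]
    maccs = FingerprintSet("MACCS", fps.matrix[:, :w].copy(),
                           fps.bit_names[:w], list(fps.compound_ids))
    ecfp = FingerprintSet("ECFP6", fps.matrix[:, w:].copy(),
                          fps.bit_names[w:], list(fps.compound_ids),
                          bit_info=fps.bit_info)
    return maccs, ecfp


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a&b| / |a|b| over binary vectors.

    Both-all-zero vectors compare as 1.0 by convention (identical empty
    bit sets).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"width mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


# --------------------------------------------------------------------------
# drug-likeness
# --------------------------------------------------------------------------

@dataclass
class PropertyRecord:
    """The four Lipinski properties."""

    mw: float
    logp: float
    hbd: int
    hba: int


def compute_properties(smiles: str) -> PropertyRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return PropertyRecord(
        mw=Descriptors.MolWt(mol),
        logp=Descriptors.MolLogP(mol),
        hbd=Descriptors.NumHDonors(mol),
        hba=Descriptors.NumHAcceptors(mol),
    )


def lipinski_violations(p: PropertyRecord) -> int:
    """Count of rule-of-five violations.

    Compliance is strict as conventionally printed (MW < 500 Da,
    LogP < 5, HBD < 5, HBA < 10), so equality counts as a violation.
    """
    for name in ("mw", "logp", "hbd", "hba"):
        if getattr(p, name) is None:
            raise ValueError(f"missing property {name!r}")
    return int(p.mw >= 500) + int(p.logp >= 5) + int(p.hbd >= 5) + int(p.hba >= 10)
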