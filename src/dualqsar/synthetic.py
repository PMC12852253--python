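"""Synthetic bioactivity tables with planted structure-activity ground truth.

The generator assembles molecules from a small versioned library of
scaffolds and substituent fragments (string substitution at marked
attachment points, then RDKit canonicalization).  Each fragment carries a
planted pIC50 contribution per target; a compound's latent potency is

    pIC50_target = baseline_target + sum(fragment weights) + N(0, noise_sd)

reported as IC50 in nM.  Fragments with large weights on *both* targets
create dual actives; the dual/non-dual imbalance is controlled by
``dual_fraction_target`` (default 0.27, i.e. roughly 1:2.7).  On top of
the clean tables, the generator injects the record pathologies a curation
pipeline must handle -- salts, mixtures, metal-containing compounds,
missing IC50 values, duplicate records with lower pIC50 -- plus
near-duplicate structural analogues (single-substituent homologations)
that exercise the Tanimoto redundancy filter.  Injected records carry a
hidden ``artifact`` flag so curation recall/precision can be scored.

Nothing here aims at realistic medicinal-chemistry diversity; the point
is a finite, fully known chemical space in which every downstream stage
is testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .curation import BioactivityTable, CompoundRecord

RDLogger.DisableLog("rdApp.*")


class ConfigurationError(ValueError):
    pass


# --------------------------------------------------------------------------
# the versioned fragment library
# --------------------------------------------------------------------------

#: scaffold SMILES templates keyed by number of attachment slots
SCAFFOLDS: dict[int, list[str]] = {
    1: [
        "c1ccc({0})cc1",
        "c1ccc2cc({0})ccc2c1",
        "c1ccc2[nH]c({0})cc2c1",
        "c1ccc2nc({0})ccc2c1",
        "C1CCN({0})CC1",
        "c1ccnc({0})c1",
        "c1csc({0})c1",
    ],
    2: [
        "c1ccc({0})c({1})c1",
        "c1cc2ccc({0})cc2cc1{1}",
    ],
    3: [
        "c1cc({0})cc({1})c1{2}",
        "O=C(Nc1ccc({0})cc1)c1cc({1})cc({2})c1OC",
    ],
}

#: fragment-ID -> (SMILES snippet, AChE weight, BACE1 weight), pIC50 units.
#: "dual" fragments drive both targets, "ache"/"bace" one target, the rest
#: are weak modulators (some deactivating).
FRAGMENTS: dict[str, tuple[str, float, float]] = {
    # dual drivers (shared between both weight maps)
    "DUAL_CARBAMATE": ("C(=O)N7CCCCC7", 2.6, 2.4),
    "DUAL_PIPERAZ_ME": ("N7CCN(C)CC7", 2.4, 2.6),
    "DUAL_PIPERAZ_ET": ("N7CCN(CC)CC7", 2.5, 2.5),
    "DUAL_BENZYL": ("Cc7ccccc7", 2.5, 2.3),
    # AChE-selective
    "ACHE_DIMETHYLAMINO": ("N(C)C", 2.1, 0.1),
    "ACHE_PHENOXY": ("Oc7ccccc7", 1.8, 0.0),
    # BACE1-selective
    "BACE_SULFONAMIDE": ("S(=O)(=O)N", 0.1, 2.2),
    "BACE_NMETHYLAMIDE": ("C(=O)NC", 0.0, 1.9),
    "BACE_NETHYLAMIDE": ("C(=O)NCC", 0.0, 1.7),
    # weak modulators
    "NEU_METHOXY": ("OC", 0.3, 0.2),
    "NEU_ETHOXY": ("OCC", 0.25, 0.15),
    "NEU_CHLORO": ("Cl", 0.2, -0.1),
    "NEU_FLUORO": ("F", -0.1, 0.1),
    "NEU_NITRILE": ("C#N", -0.5, -0.4),
    "NEU_ETHYL": ("CC", 0.1, 0.0),
    "NEU_PROPYL": ("CCC", 0.0, -0.2),
    "NEU_OCF3": ("OC(F)(F)F", -0.7, -0.6),
    "NEU_MORPHOLINE": ("N7CCOCC7", 0.3, 0.2),
    "NEU_PHENYL": ("c7ccccc7", 0.4, 0.25),
}

DUAL_POOL = ["DUAL_CARBAMATE", "DUAL_PIPERAZ_ME", "DUAL_PIPERAZ_ET", "DUAL_BENZYL"]
ACHE_POOL = ["ACHE_DIMETHYLAMINO", "ACHE_PHENOXY"]
BACE_POOL = ["BACE_SULFONAMIDE", "BACE_NMETHYLAMIDE", "BACE_NETHYLAMIDE"]
NEUTRAL_POOL = [f for f in FRAGMENTS if f.startswith("NEU_")]
#: mild subset used alongside strong drivers so planted actives stay active
MILD_POOL = [
    "NEU_METHOXY", "NEU_ETHOXY", "NEU_CHLORO", "NEU_FLUORO",
    "NEU_ETHYL", "NEU_PROPYL", "NEU_MORPHOLINE", "NEU_PHENYL",
]

#: single-substituent homologation swaps used for near-duplicate analogues
ANALOGUE_SWAPS = {
    "NEU_METHOXY": "NEU_ETHOXY",
    "NEU_ETHYL": "NEU_PROPYL",
    "DUAL_PIPERAZ_ME": "DUAL_PIPERAZ_ET",
    "BACE_NMETHYLAMIDE": "BACE_NETHYLAMIDE",
}

SALT_COUNTERIONS = ["Cl", "[Na+]", "OC(=O)C(=O)O"]
METAL_SMILES = ["CC[Fe]CC", "CC[Zn]CC", "CC[Hg]CC"]


@dataclass
class FragmentLibrary:
    fragments: dict[str, str] = field(
        default_factory=lambda: {k: v[0] for k, v in FRAGMENTS.items()}
    )
    scaffolds: dict[int, list[str]] = field(default_factory=lambda: dict(SCAFFOLDS))


@dataclass
class ActivityGroundTruth:
    """Planted fragment weights plus (after generation) provenance maps."""

    weights_ache: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in FRAGMENTS.items()}
    )
    weights_bace: dict[str, float] = field(
        default_factory=lambda: {k: v[2] for k, v in FRAGMENTS.items()}
    )
    baseline_ache: float = 4.8
    baseline_bace: float = 4.8
    noise_sd: float = 0.30
    shared_fragments: list[str] = field(default_factory=lambda: list(DUAL_POOL))
    # populated by generate_library
    compound_fragments: dict[str, list[str]] = field(default_factory=dict)
    compound_smiles: dict[str, str] = field(default_factory=dict)
    true_pic50_ache: dict[str, float] = field(default_factory=dict)
    true_pic50_bace: dict[str, float] = field(default_factory=dict)
    true_label: dict[str, int] = field(default_factory=dict)
    analogue_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for f in self.shared_fragments:
            if f not in self.weights_ache or f not in self.weights_bace:
                raise ConfigurationError(
                    f"shared fragment {f!r} missing from a weight map"
                )

    def fragment_matrix(self, compound_ids=None):
        """Binary compound x fragment indicator matrix for recovery tests."""
        if compound_ids is None:
            compound_ids = list(self.compound_fragments)
        frag_ids = sorted(self.weights_ache)
        idx = {f: j for j, f in enumerate(frag_ids)}
        X = np.zeros((len(compound_ids), len(frag_ids)), dtype=np.uint8)
        for i, cid in enumerate(compound_ids):
            for f in self.compound_fragments.get(cid, []):
                X[i, idx[f]] = 1
        return X, frag_ids

    def top_weighted_fragments(self, target: str = "ache", k: int = 10):
        w = self.weights_ache if target == "ache" else self.weights_bace
        return sorted(w, key=lambda f: abs(w[f]), reverse=True)[:k]


@dataclass
class GeneratorConfig:
    n_compounds: int = 500
    dual_fraction_target: float = 0.27
    overlap_fraction: float = 0.5
    noise_sd: float = 0.30
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {
            "salt": 0.03, "mixture": 0.02, "metal": 0.02,
            "missing_ic50": 0.03, "duplicate": 0.05,
        }
    )
    analogue_rate: float = 0.06
    seed: int = 0

    def validate(self) -> None:
        props = [self.dual_fraction_target, self.overlap_fraction,
                 self.analogue_rate, *self.artifact_rates.values()]
        if not all(0.0 <= p <= 1.0 for p in props):
            raise ConfigurationError("all proportions must lie in [0, 1]")
        if not (0.0 < self.dual_fraction_target < 1.0):
            raise ConfigurationError("dual_fraction_target must be in (0,1)")
        if self.n_compounds < 1:
            raise ConfigurationError("n_compounds must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def assemble(scaffold: str, sub_smiles: list[str]) -> str:
    """Fill a scaffold's attachment slots and canonicalize."""
    smi = scaffold.format(*sub_smiles)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:  # library invariant: every product is valid
        raise ConfigurationError(f"invalid assembly {smi!r}")
    return Chem.MolToSmiles(mol)


def _pick_fragments(rng: np.random.Generator, mode: str) -> list[str]:
    n_extra = int(rng.integers(0, 3))  # 0-2 weak modulators
    if mode == "dual":
        core = [str(rng.choice(DUAL_POOL))]
        extra_pool = MILD_POOL
    elif mode == "ache":
        core = [str(rng.choice(ACHE_POOL))]
        extra_pool = NEUTRAL_POOL
    elif mode == "bace":
        core = [str(rng.choice(BACE_POOL))]
        extra_pool = NEUTRAL_POOL
    else:  # inactive
        core = []
        n_extra = int(rng.integers(1, 4))  # 1-3 modulators
        extra_pool = NEUTRAL_POOL
    extra = list(rng.choice(extra_pool, size=n_extra, replace=False)) if n_extra else []
    frags = core + [str(f) for f in extra]
    rng.shuffle(frags)
    return frags[:3]


def _latent_pic50(truth: ActivityGroundTruth, frags, rng, noise_sd):
    pa = truth.baseline_ache + sum(truth.weights_ache[f] for f in frags)
    pb = truth.baseline_bace + sum(truth.weights_bace[f] for f in frags)
    if noise_sd > 0:
        pa += rng.normal(0.0, noise_sd)
        pb += rng.normal(0.0, noise_sd)
    return pa, pb


def _record(cid, smiles, pic50, target, artifact=None):
    ic50 = 10.0 ** (-pic50) if pic50 is not None else None
    rec = CompoundRecord(compound_id=cid, smiles=smiles, target_id=target,
                         ic50=ic50)
    rec.artifact = artifact
    return rec


def generate_library(
    config: GeneratorConfig | None = None,
    truth: ActivityGroundTruth | None = None,
    inject: bool = True,
) -> tuple[BioactivityTable, BioactivityTable, ActivityGroundTruth]:
    """Generate the AChE and BACE1 bioactivity tables plus ground truth.

    Identical ``config`` (including seed) yields byte-identical tables.
    With ``inject=True`` the artifact and analogue records configured in
    ``config`` are appended (flagged via the hidden ``artifact`` field).
    """
    config = config or GeneratorConfig()
    config.validate()
    truth = truth or ActivityGroundTruth()
    truth.noise_sd = config.noise_sd
    rng = np.random.default_rng(config.seed)

    seen: set[str] = set()
    compounds = []  # (cid, smiles, membership, frags, pa, pb)
    i = 0
    while len(compounds) < config.n_compounds:
        cid = f"SYN{i:06d}"
        i += 1
        membership = "both" if rng.random() < config.overlap_fraction else (
            "ache" if rng.random() < 0.5 else "bace")
        if membership == "both":
            mode = "dual" if rng.random() < config.dual_fraction_target else str(
                rng.choice(["ache", "bace", "inactive"]))
        else:
            # single-table compounds: half active on their own target
            mode = membership if rng.random() < 0.5 else "inactive"
        # retry assembly (not the mode draw) on structure collisions, so
        # the realized mode mix is not biased toward modes with larger
        # combinatorial spaces
        smiles = None
        for _attempt in range(60):
            frags = _pick_fragments(rng, mode)
            if not frags:
                frags = ["NEU_ETHYL"]
            scaffold = str(rng.choice(SCAFFOLDS[len(frags)]))
            candidate = assemble(scaffold, [FRAGMENTS[f][0] for f in frags])
            if candidate not in seen:
                smiles = candidate
                break
        if smiles is None:  # space for this mode exhausted; redraw compound
            continue
        seen.add(smiles)
        pa, pb = _latent_pic50(truth, frags, rng, config.noise_sd)
        compounds.append((cid, smiles, membership, frags, pa, pb, scaffold))
        truth.compound_fragments[cid] = list(frags)
        truth.compound_smiles[cid] = smiles
        truth.true_pic50_ache[cid] = pa
        truth.true_pic50_bace[cid] = pb
        truth.true_label[cid] = int(pa > 6.0 and pb > 6.0)

    ache_records = [
        _record(cid, smi, pa, "ACHE")
        for cid, smi, mem, _, pa, _, _ in compounds if mem in ("both", "ache")
    ]
    bace_records = [
        _record(cid, smi, pb, "BACE1")
        for cid, smi, mem, _, _, pb, _ in compounds if mem in ("both", "bace")
    ]

    # near-duplicate analogues: single-substituent homologation swaps on the
    # largest eligible molecules (big shared context keeps Tanimoto >= 0.8),
    # rebuilt on the base compound's own scaffold
    n_analog = round(config.analogue_rate * config.n_compounds)
    if n_analog:
        eligible = [c for c in compounds
                    if any(f in ANALOGUE_SWAPS for f in c[3])]
        eligible.sort(key=lambda c: -len(c[1]))  # biggest molecules first
        for j, (cid, smi, mem, frags, _, _, scaffold) in enumerate(
                eligible[:n_analog]):
            new_frags = [ANALOGUE_SWAPS.get(f, f) for f in frags]
            new_smi = assemble(scaffold, [FRAGMENTS[f][0] for f in new_frags])
            if new_smi in seen:
                continue
            seen.add(new_smi)
            acid = f"ANA{j:04d}"
            pa, pb = _latent_pic50(truth, new_frags, rng, config.noise_sd)
            truth.compound_fragments[acid] = list(new_frags)
            truth.compound_smiles[acid] = new_smi
            truth.true_pic50_ache[acid] = pa
            truth.true_pic50_bace[acid] = pb
            truth.true_label[acid] = int(pa > 6.0 and pb > 6.0)
            truth.analogue_pairs.append((cid, acid))
            if mem in ("both", "ache"):
                ache_records.append(_record(acid, new_smi, pa, "ACHE", "analogue"))
            if mem in ("both", "bace"):
                bace_records.append(_record(acid, new_smi, pb, "BACE1", "analogue"))

    ache = BioactivityTable(records=ache_records)
    bace = BioactivityTable(records=bace_records)
    if inject:
        inject_artifacts(ache, config, rng)
        inject_artifacts(bace, config, rng)
    ache.log_step("raw")
    bace.log_step("raw")
    return ache, bace, truth


def inject_artifacts(
    table: BioactivityTable,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> BioactivityTable:
    """Append flagged pathological records (hidden from curation).

    salt/mixture: extra disconnected component; metal: organometallic
    SMILES; missing_ic50: no activity value; duplicate: same compound_id
    with a strictly lower pIC50.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    clean = [r for r in table.records if r.artifact is None]
    if not clean:
        return table
    n = len(clean)
    counter = 0
    for kind, rate in config.artifact_rates.items():
        k = round(rate * n)
        if k == 0:
            continue
        bases = rng.choice(len(clean), size=min(k, n), replace=False)
        for b in bases:
            base = clean[int(b)]
            pic50 = float(rng.normal(5.5, 1.0))
            cid = f"ART{counter:05d}"
            counter += 1
            if kind == "salt":
                ion = str(rng.choice(SALT_COUNTERIONS))
                rec = _record(cid, f"{base.smiles}.{ion}", pic50,
                              base.target_id, "salt")
            elif kind == "mixture":
                other = clean[int(rng.integers(0, n))]
                rec = _record(cid, f"{base.smiles}.{other.smiles}", pic50,
                              base.target_id, "mixture")
            elif kind == "metal":
                rec = _record(cid, str(rng.choice(METAL_SMILES)), pic50,
                              base.target_id, "metal")
            elif kind == "missing_ic50":
                rec = _record(cid, base.smiles if rng.random() < 0.5
                              else assemble("c1ccc({0})cc1", ["OC"]),
                              None, base.target_id, "missing_ic50")
            elif kind == "duplicate":
                low = base.pic50 - float(rng.uniform(0.5, 2.0))
                rec = _record(base.compound_id, base.smiles, low,
                              base.target_id, "duplicate")
            else:
                raise ConfigurationError(f"unknown artifact kind {kind!r}")
            table.records.append(rec)
    # deterministic shuffle so artifacts are not trivially positional
    order = rng.permutation(len(table.records))
    table.records = [table.records[int(i)] for i in order]
    return table


def curation_scores(table: BioactivityTable,
                    truth: ActivityGroundTruth | None = None) -> dict:
    """Score a curated table against the hidden injection flags.

    Returns artifact recall (fraction of injected artifact records that
    were removed) and the fraction of clean records removed.  Analogue
    records -- and, when ``truth`` is given, their base compounds -- are
    excluded from both scores: the redundancy filter removes one member
    of each near-duplicate pair by design, and which member survives
    depends only on record order.
    """
    analogue_bases = (
        {base for base, _ana in truth.analogue_pairs} if truth else set()
    )
    artifacts = [r for r in table.records
                 if r.artifact not in (None, "analogue")]
    clean = [r for r in table.records
             if r.artifact is None and r.compound_id not in analogue_bases]
    recall = (sum(1 for r in artifacts if not r.kept) / len(artifacts)
              if artifacts else float("nan"))
    clean_removed = (sum(1 for r in clean if not r.kept) / len(clean)
                     if clean else float("nan"))
    return {
        "artifact_recall": recall,
        "clean_removed_fraction": clean_removed,
        "n_artifacts": len(artifacts),
        "n_clean": len(clean),
    }
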