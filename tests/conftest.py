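"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pytest

from dualqsar import curation
from dualqsar.featurize import compute_fingerprints
from dualqsar.synthetic import GeneratorConfig, generate_library


def ecfp(smiles, ids):
    return compute_fingerprints(smiles, "ECFP6", ids)


@pytest.fixture(scope="session")
def small_study():
    """Raw synthetic tables + ground truth, 250 compounds, seed 0."""
    return generate_library(GeneratorConfig(n_compounds=250, seed=0))


@pytest.fixture(scope="session")
def curated_study(small_study):
    """Curated copy of the small study plus its dual dataset."""
    ache, bace, truth = generate_library(GeneratorConfig(n_compounds=250,
                                                         seed=0))
    curation.curate(ache, ecfp)
    curation.curate(bace, ecfp)
    dual = curation.build_dual_dataset(ache, bace)
    return ache, bace, dual, truth


@pytest.fixture(scope="session")
def canary_features():
    """Large fully-overlapping dual dataset for the leakage canary.

    The hold-out must be big enough (~100 compounds) that a genuinely
    uninformative model's |MCC| sampling noise sits well below the
    leakage bound."""
    ache, bace, _ = generate_library(
        GeneratorConfig(n_compounds=420, overlap_fraction=1.0, seed=5))
    curation.curate(ache, ecfp)
    curation.curate(bace, ecfp)
    dual = curation.build_dual_dataset(ache, bace)
    smiles = {r.compound_id: r.smiles for r in ache.kept_records()}
    fps = compute_fingerprints([smiles[c] for c in dual.compound_ids],
                               "ECFP6", dual.compound_ids)
    return fps.matrix.astype(float), dual.labels


@pytest.fixture(scope="session")
def dual_features(curated_study):
    """ECFP6 matrix aligned with the dual dataset rows."""
    ache, _, dual, _ = curated_study
    smiles = {r.compound_id: r.smiles for r in ache.kept_records()}
    fps = compute_fingerprints([smiles[c] for c in dual.compound_ids],
                               "ECFP6", dual.compound_ids)
    return fps.matrix.astype(float), dual.labels
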