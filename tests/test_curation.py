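"""Curation rules: pIC50 transform, validity filters, duplicates, redundancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualqsar.curation import (
    BioactivityTable,
    CompoundRecord,
    CurationError,
    build_dual_dataset,
    diversity_stats,
    filter_invalid,
    potency_consistency,
    redundancy_filter,
    resolve_duplicates,
    to_pic50,
)
from dualqsar.featurize import FingerprintSet


def rec(cid, smiles="CCO", pic50=6.5, target="ACHE", ic50=None):
    if ic50 is None and pic50 is not None:
        ic50 = 10.0 ** (-pic50)
    return CompoundRecord(compound_id=cid, smiles=smiles, target_id=target,
                          ic50=ic50)


@pytest.mark.parametrize("ic50, expected", [
    (1e-6, 6.0),          # 1 uM, the dual-activity threshold
    (1.0, 0.0),
    (21.79e-9, 7.6617),   # hand -log10
])
def test_to_pic50_values(ic50, expected):
    assert to_pic50(ic50) == pytest.approx(expected, abs=1e-4)


def test_to_pic50_rejects_nonpositive():
    for bad in (0.0, -1e-6, float("nan")):
        with pytest.raises(ValueError):
            to_pic50(bad)


@given(st.floats(min_value=-2.0, max_value=12.0))
@settings(max_examples=50, deadline=None)
def test_pic50_roundtrip_identity(p):
    assert to_pic50(10.0 ** (-p)) == pytest.approx(p, abs=1e-9)


@pytest.mark.parametrize("smiles, reason", [
    ("CC(=O)O.[Na+]", "salt_or_mixture"),
    ("CC[Fe]CC", "metal"),
    ("not a smiles", "parse_error"),
])
def test_filter_invalid_reasons(smiles, reason):
    t = BioactivityTable(records=[rec("A", smiles=smiles)])
    filter_invalid(t)
    assert t.records[0].status == f"removed:{reason}"


def test_filter_invalid_keeps_clean_organic():
    t = BioactivityTable(records=[
        rec("A", smiles="c1ccccc1CCN"),
        rec("B", smiles="CCO", pic50=None, ic50=None),  # no IC50
        rec("C", smiles="CC(F)CC"),  # unspecified stereocenter
    ])
    filter_invalid(t)
    assert t.records[0].kept
    assert t.records[1].status == "removed:missing_ic50"
    assert t.records[2].status == "removed:ambiguous_stereo"


def test_resolve_duplicates_keeps_max_and_first_on_tie():
    t = BioactivityTable(records=[
        rec("A", pic50=6.1), rec("A", pic50=5.2),
        rec("B", pic50=7.0), rec("B", pic50=7.0),
        rec("C", pic50=5.5),
    ])
    resolve_duplicates(t)
    kept = [(r.compound_id, r.pic50) for r in t.kept_records()]
    assert kept == [("A", pytest.approx(6.1)), ("B", pytest.approx(7.0)),
                    ("C", pytest.approx(5.5))]
    # tie kept the *first* B record in input order
    assert t.records[2].kept and not t.records[3].kept


def _fps(rows, ids):
    m = np.array(rows, dtype=np.uint8)
    return FingerprintSet("ECFP6", m, [f"b{i}" for i in range(m.shape[1])],
                          ids)


def test_redundancy_filter_greedy_chain():
    """A~B and B~C above threshold but A~C below: survivors are {A, C}."""
    width = 12
    A = [1] * 10 + [0, 0]
    B = [1] * 9 + [0, 1, 0]            # T(A,B) = 9/11 = 0.818
    C = [1] * 8 + [0, 0, 1, 1]         # T(B,C) = 9/11, T(A,C) = 8/12 = 0.667
    t = BioactivityTable(records=[rec("A"), rec("B"), rec("C")])
    redundancy_filter(t, _fps([A, B, C], ["A", "B", "C"]), threshold=0.80)
    assert [r.compound_id for r in t.kept_records()] == ["A", "C"]


def test_redundancy_filter_idempotent_and_no_close_pair_survives():
    rng = np.random.default_rng(1)
    rows = (rng.random((30, 64)) < 0.3).astype(np.uint8)
    rows[5] = rows[0]  # exact duplicate must be caught
    ids = [f"C{i}" for i in range(30)]
    t1 = BioactivityTable(records=[rec(i) for i in ids])
    fps = _fps(rows, ids)
    redundancy_filter(t1, fps, threshold=0.80)
    kept1 = [r.compound_id for r in t1.kept_records()]
    from dualqsar.featurize import tanimoto
    kept_rows = [rows[ids.index(c)] for c in kept1]
    for i in range(len(kept_rows)):
        for j in range(i + 1, len(kept_rows)):
            assert tanimoto(kept_rows[i], kept_rows[j]) < 0.80
    t2 = BioactivityTable(records=[rec(i) for i in kept1])
    redundancy_filter(t2, fps, threshold=0.80)
    assert [r.compound_id for r in t2.kept_records()] == kept1


def test_redundancy_filter_missing_fingerprint_names_record():
    t = BioactivityTable(records=[rec("A"), rec("ZZZ")])
    with pytest.raises(CurationError, match="ZZZ"):
        redundancy_filter(t, _fps([[1, 0]], ["A"]))


def test_audit_counts_never_increase(curated_study):
    ache, bace, _, _ = curated_study
    for table in (ache, bace):
        counts = list(table.audit.values())
        assert all(b <= a for a, b in zip(counts, counts[1:]))


@pytest.mark.parametrize("pa, pb, label", [
    (7.38, 7.21, 1),   # class-1 mean profile
    (6.0, 8.0, 0),     # boundary: strictly greater than 6 required
    (5.0, 5.0, 0),
])
def test_dual_labeling_rule(pa, pb, label):
    a = BioactivityTable(records=[rec("X", pic50=pa, target="ACHE")])
    b = BioactivityTable(records=[rec("X", pic50=pb, target="BACE1")])
    dual = build_dual_dataset(a, b)
    assert dual.entries.loc[0, "label"] == label


def test_dual_dataset_intersection_and_empty_warning():
    a = BioactivityTable(records=[rec("X"), rec("Y")])
    b = BioactivityTable(records=[rec("Y"), rec("Z")])
    dual = build_dual_dataset(a, b)
    assert dual.compound_ids == ["Y"]
    with pytest.warns(UserWarning):
        empty = build_dual_dataset(
            BioactivityTable(records=[rec("P")]),
            BioactivityTable(records=[rec("Q")]))
    assert len(empty) == 0


@pytest.mark.parametrize("n, n_pairs", [(55, 1485), (149, 11026)])
def test_diversity_pair_counts(n, n_pairs):
    rng = np.random.default_rng(0)
    fps = _fps((rng.random((n, 32)) < 0.4).astype(np.uint8),
               [f"C{i}" for i in range(n)])
    assert diversity_stats(fps).n_pairs == n_pairs


def test_diversity_identical_fingerprints():
    fps = _fps([[1, 0, 1]] * 3, ["A", "B", "C"])
    d = diversity_stats(fps, cutoff=0.7)
    assert d.mean_sim == d.median_sim == 1.0
    assert d.frac_above == 1.0
    with pytest.raises(CurationError):
        diversity_stats(_fps([[1, 0]], ["A"]))


def test_potency_consistency_counts():
    a = BioactivityTable(records=[
        rec("A", pic50=6.5), rec("B", pic50=6.5), rec("C", pic50=5.0)])
    b = BioactivityTable(records=[
        rec("A", pic50=6.4, target="BACE1"),
        rec("B", pic50=7.2, target="BACE1"),
        rec("C", pic50=5.0, target="BACE1")])
    dual = build_dual_dataset(a, b)
    count, prop = potency_consistency(dual, delta=0.5)
    assert (count, prop) == (1, 0.5)  # |6.5-6.4| counted, |6.5-7.2| not


def test_potency_consistency_brute_force(curated_study):
    _, _, dual, _ = curated_study
    count, prop = potency_consistency(dual, delta=0.5)
    pos = dual.entries[dual.entries["label"] == 1]
    brute = int(sum(abs(r.pic50_ache - r.pic50_bace) < 0.5
                    for r in pos.itertuples()))
    assert count == brute
    assert prop == pytest.approx(brute / len(pos))


def test_table_csv_roundtrip(tmp_path, small_study):
    ache, _, _ = small_study
    path = tmp_path / "t.csv"
    ache.to_csv(path, kept_only=False)
    back = BioactivityTable.read_csv(path, target_id="ACHE")
    assert len(back) == len(ache.records)
    orig = [r for r in ache.records if r.ic50 is not None]
    loaded = [r for r in back.records if r.ic50 is not None]
    for r1, r2 in zip(orig, loaded):
        assert r2.pic50 == pytest.approx(r1.pic50, abs=1e-9)
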