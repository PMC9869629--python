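import pytest

from classlink.aggregation import (
    CANOPUS,
    MOLNETENHANCER,
    ClassPrediction,
    GCFRecord,
    InvalidRecordError,
    InvalidSourceError,
    MFRecord,
    MissingPredictionError,
    apply_canopus_cutoffs,
    assign_gcf_classes,
    assign_mf_classes,
    select_spectrum_classes,
)
from classlink.ontology import ANTISMASH_CLASS, CF_SUPERCLASS, MIBIG_CLASS, NPC_PATHWAY


def make_gcf(classes_per_bgc, bigscape_class="PKSI"):
    members = [f"b{i}" for i in range(len(classes_per_bgc))]
    return GCFRecord(
        gcf_id="g1",
        member_bgc_ids=members,
        bigscape_class=bigscape_class,
        antismash_classes_per_bgc=dict(zip(members, classes_per_bgc)),
    )


def test_gcf_majority_rule_drops_minority_class():
    cs = assign_gcf_classes(make_gcf([["t1pks"], ["t1pks", "nrps"], ["t1pks"]]))
    assert cs.labels(ANTISMASH_CLASS) == ["t1pks"]  # nrps at 1/3 dropped
    assert cs.labels(MIBIG_CLASS) == ["Polyketide"]


def test_gcf_half_is_inclusive():
    cs = assign_gcf_classes(make_gcf([["t1pks"], ["t1pks"], ["nrps"], ["nrps"]]))
    assert set(cs.labels(ANTISMASH_CLASS)) == {"t1pks", "nrps"}  # 2/4 kept


def test_gcf_single_member_keeps_all():
    cs = assign_gcf_classes(make_gcf([["t1pks", "indole"]]))
    assert set(cs.labels(ANTISMASH_CLASS)) == {"t1pks", "indole"}


def test_gcf_antismash_ordered_by_frequency():
    cs = assign_gcf_classes(make_gcf([["nrps"], ["nrps", "t1pks"], ["nrps", "t1pks"], ["t1pks", "nrps"]]))
    assert cs.labels(ANTISMASH_CLASS) == ["nrps", "t1pks"] or cs.labels(ANTISMASH_CLASS)[0] == "nrps"


def test_gcf_hybrid_bigscape_class_stays_grouped():
    cs = assign_gcf_classes(make_gcf([["t1pks"]], bigscape_class="PKS-NRP_Hybrids"))
    assert cs.labels(MIBIG_CLASS) == ["Polyketide-NRP"]


def test_gcf_invariant_under_member_reordering():
    classes = [["t1pks"], ["nrps", "t1pks"], ["nrps"], ["t1pks"]]
    a = assign_gcf_classes(make_gcf(classes))
    b = assign_gcf_classes(make_gcf(classes[::-1]))
    assert a.labels(ANTISMASH_CLASS) == b.labels(ANTISMASH_CLASS)


def test_empty_gcf_rejected():
    with pytest.raises(InvalidRecordError):
        GCFRecord("g", [], "PKSI")


def _pred(source, object_id="s1"):
    return ClassPrediction(object_id, source)


@pytest.mark.parametrize(
    "mass, has_canopus, has_mne, expected",
    [
        (500.0, True, True, CANOPUS),
        (900.0, True, True, MOLNETENHANCER),
        (500.0, False, True, MOLNETENHANCER),
        (850.0, True, False, CANOPUS),  # boundary inclusive
        (900.0, True, False, None),
        (500.0, False, False, None),
    ],
)
def test_source_selection(mass, has_canopus, has_mne, expected):
    got = select_spectrum_classes(
        _pred(CANOPUS) if has_canopus else None,
        _pred(MOLNETENHANCER) if has_mne else None,
        mass,
    )
    assert (got.source if got else None) == expected


def test_source_selection_single_source_modes():
    c, m = _pred(CANOPUS), _pred(MOLNETENHANCER)
    assert select_spectrum_classes(c, m, 500.0, "canopus_only") is c
    assert select_spectrum_classes(c, m, 500.0, "mne_only") is m
    assert select_spectrum_classes(None, m, 500.0, "canopus_only") is None


def test_canopus_cutoffs():
    pred = ClassPrediction("s1", CANOPUS)
    pred.terms_by_scheme[CF_SUPERCLASS] = [("A", 0.6), ("B", 0.49)]
    pred.terms_by_scheme[NPC_PATHWAY] = [("x", 0.34), ("y", 0.9), ("z", 0.3)]
    out = apply_canopus_cutoffs(pred)
    assert out.terms_by_scheme[CF_SUPERCLASS] == [("A", 0.6)]
    # NPC terms above 0.33 kept and sorted by probability descending
    assert out.terms_by_scheme[NPC_PATHWAY] == [("y", 0.9), ("x", 0.34)]


def test_canopus_cutoffs_all_below_keeps_empty_lists():
    pred = ClassPrediction("s1", CANOPUS)
    pred.terms_by_scheme[CF_SUPERCLASS] = [("A", 0.1)]
    out = apply_canopus_cutoffs(pred)
    assert out.terms_by_scheme[CF_SUPERCLASS] == []


def test_canopus_cutoffs_wrong_source():
    with pytest.raises(InvalidSourceError):
        apply_canopus_cutoffs(_pred(MOLNETENHANCER))


def _mf_preds(labels_per_spectrum, scheme=NPC_PATHWAY, source=CANOPUS):
    preds = {}
    for i, labels in enumerate(labels_per_spectrum):
        p = ClassPrediction(f"s{i}", source)
        p.terms_by_scheme[scheme] = [(l, 0.9) for l in labels]
        preds[f"s{i}"] = p
    mf = MFRecord("mf1", list(preds))
    return mf, preds


def test_mf_20pct_boundary_inclusive():
    mf, preds = _mf_preds([["Polyketides"], [], [], [], []])  # 1/5 = 20%
    cs = assign_mf_classes(mf, preds)
    assert cs.labels(NPC_PATHWAY) == ["Polyketides"]


def test_mf_below_threshold_dropped():
    mf, preds = _mf_preds([["Polyketides"], [], [], [], [], []])  # 1/6 < 20%
    cs = assign_mf_classes(mf, preds)
    assert cs.labels(NPC_PATHWAY) == []


def test_mf_counting_matches_brute_force():
    import numpy as np

    rng = np.random.default_rng(17)
    vocab = ["a", "b", "c", "d"]
    labels = [list(rng.choice(vocab, size=rng.integers(0, 4), replace=False)) for _ in range(10)]
    mf, preds = _mf_preds(labels)
    kept = set(assign_mf_classes(mf, preds).labels(NPC_PATHWAY))
    freq = {v: sum(v in ls for ls in labels) for v in vocab}
    assert kept == {v for v, c in freq.items() if c / 10 >= 0.20}


def test_mf_npc_ordered_by_occurrence():
    mf, preds = _mf_preds([["a", "b"], ["b"], ["b"], ["a"], []])
    assert assign_mf_classes(mf, preds).labels(NPC_PATHWAY) == ["b", "a"]


def test_mf_missing_member_raises():
    mf, preds = _mf_preds([["a"], ["a"]])
    del preds["s1"]
    with pytest.raises(MissingPredictionError):
        assign_mf_classes(mf, preds)


def test_mf_member_without_prediction_counts_as_empty():
    mf, preds = _mf_preds([["a"], ["a"], ["a"]])
    preds["s2"] = None
    cs = assign_mf_classes(mf, preds)
    assert cs.labels(NPC_PATHWAY) == ["a"]


def test_mf_threshold_anti_monotone():
    mf, preds = _mf_preds([["a", "b"], ["b"], ["b"], ["a"], ["c"]])
    kept = [
        set(assign_mf_classes(mf, preds, threshold=t).labels(NPC_PATHWAY))
        for t in (0.0, 0.2, 0.4, 0.6, 1.0)
    ]
    for lo, hi in zip(kept[1:], kept[:-1]):
        assert lo <= hi


def test_mf_invariant_under_member_reordering():
    mf, preds = _mf_preds([["a", "b"], ["b"], ["a"], []])
    mf_rev = MFRecord("mf1", mf.member_spectrum_ids[::-1])
    assert set(assign_mf_classes(mf, preds).labels(NPC_PATHWAY)) == set(
        assign_mf_classes(mf_rev, preds).labels(NPC_PATHWAY)
    )


def test_output_terms_subset_of_inputs():
    """Source selection and thresholds never fabricate terms."""
    pred = ClassPrediction("s1", CANOPUS)
    pred.terms_by_scheme[NPC_PATHWAY] = [("x", 0.8), ("y", 0.2)]
    out = apply_canopus_cutoffs(pred)
    for scheme, terms in out.terms_by_scheme.items():
        assert {l for l, _ in terms} <= {l for l, _ in pred.terms_by_scheme[scheme]}
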