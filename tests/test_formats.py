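import json

import pandas as pd
import pytest

from classlink.aggregation import CANOPUS, MOLNETENHANCER
from classlink.formats import (
    CANOPUS_SCHEME_COLUMNS,
    DialectError,
    ParseError,
    build_gcf_records,
    load_dataset,
    read_annotated_entries,
    read_bigscape_clustering,
    read_canopus_summary,
    read_class_predictions,
    read_mgf_masses,
    read_mne_table,
    read_network_components,
    read_strain_mapping,
    read_wide_score_table,
    resolve_strain,
    write_bundle,
    write_mgf_stub,
    write_prediction_table,
)
from classlink.ontology import CF_SUPERCLASS, MIBIG_CLASS, NPC_PATHWAY
from classlink.tables import EmptyInputError


def test_read_annotated_entries_json(tmp_path):
    path = tmp_path / "entries.json"
    path.write_text(json.dumps([
        {"entry_id": "E1",
         "genome_classes": {"MIBIG_CLASS": ["Polyketide-NRP-Other"]},
         "structure_classes": {"NPC_PATHWAY": ["Polyketides"]}},
        {"entry_id": "E2",
         "genome_classes": {"MIBIG_CLASS": ["Terpene"]},
         "structure_classes": {"NPC_PATHWAY": ["Terpenoids"]}},
        {"entry_id": "E3", "genome_classes": {}, "structure_classes": {}},
    ]))
    entries = read_annotated_entries(path)
    # hybrid split applied; the all-empty entry is dropped
    assert [e.entry_id for e in entries] == ["E1", "E2"]
    assert entries[0].genome_classes.labels(MIBIG_CLASS) == ["Polyketide-NRP", "Other"]


def test_read_annotated_entries_tsv(tmp_path):
    path = tmp_path / "entries.tsv"
    path.write_text(
        "entry_id\tscheme\tlabel\n"
        "E1\tMIBIG_CLASS\tPolyketide\n"
        "E1\tNPC_PATHWAY\tPolyketides\n"
    )
    entries = read_annotated_entries(path)
    assert len(entries) == 1
    assert entries[0].structure_classes.labels(NPC_PATHWAY) == ["Polyketides"]


def test_read_annotated_entries_empty_raises(tmp_path):
    path = tmp_path / "empty.json"
    path.write_text("[]")
    with pytest.raises(EmptyInputError):
        read_annotated_entries(path)


def test_read_annotated_entries_malformed(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text('[{"genome_classes": {}}]')
    with pytest.raises(ParseError):
        read_annotated_entries(path)


def test_bigscape_clustering(tmp_path):
    path = tmp_path / "c.tsv"
    path.write_text(
        "BGC Name\tFamily Number\n"
        "b1\tF1\nb2\tF1\nb3\tF2\nb4\tF2\nb5\tF1\nb5\tF1\n"
    )
    mapping = read_bigscape_clustering(path)
    assert len(mapping) == 5 and mapping["b5"] == "F1"
    path.write_text("BGC Name\tFamily Number\nb1\tF1\nb1\tF2\n")
    with pytest.raises(ParseError):
        read_bigscape_clustering(path)
    path.write_text("wrong\tcols\nb1\tF1\n")
    with pytest.raises(DialectError):
        read_bigscape_clustering(path)


def test_build_gcf_records_assembly():
    records = build_gcf_records(
        {"PKSI": {"b1": "F1", "b2": "F1"}, "NRPS": {"b3": "F2"}},
        {"b1": ["t1pks"], "b3": ["nrps"]},
    )
    by_id = {r.gcf_id: r for r in records}
    assert by_id["F1"].bigscape_class == "PKSI"
    assert by_id["F1"].member_bgc_ids == ["b1", "b2"]
    assert by_id["F1"].antismash_classes_per_bgc["b2"] == []


def test_mgf_round_trip(tmp_path):
    path = tmp_path / "spectra.mgf"
    masses = {"101": 350.5, "102": 900.25}
    write_mgf_stub(masses, path)
    assert read_mgf_masses(path) == masses


def test_mgf_missing_pepmass(tmp_path):
    path = tmp_path / "bad.mgf"
    path.write_text("BEGIN IONS\nSCANS=7\n100.0 1.0\nEND IONS\n")
    with pytest.raises(ParseError, match="7"):
        read_mgf_masses(path)


def test_network_components_and_singletons(tmp_path):
    path = tmp_path / "net.tsv"
    path.write_text(
        "cluster index\tcomponentindex\n"
        "s1\t3\ns2\t3\ns3\t-1\ns4\t5\n"
    )
    mfs = read_network_components(path)
    assert mfs["3"] == ["s1", "s2"]
    assert mfs["singleton_s3"] == ["s3"]
    assert mfs["5"] == ["s4"]


def test_strain_mapping_and_resolution(tmp_path):
    path = tmp_path / "strains.csv"
    path.write_text("CNS205,CNS205.mzXML,NC_009953\nCNS237,CNS237.mzXML\n")
    maps = read_strain_mapping(path)
    assert resolve_strain("CNS205.mzXML", maps) == "CNS205"
    assert resolve_strain("NC_009953.1.region013", maps) == "CNS205"
    assert resolve_strain("unrelated", maps) is None


def test_prediction_tables_round_trip(tmp_path):
    from classlink.aggregation import ClassPrediction

    pred = ClassPrediction("s1", CANOPUS)
    pred.terms_by_scheme[NPC_PATHWAY] = [("Polyketides", 0.91), ("Alkaloids", 0.35)]
    pred.terms_by_scheme[CF_SUPERCLASS] = [("Benzenoids", 0.8)]
    path = tmp_path / "canopus_summary.tsv"
    write_prediction_table({"s1": pred}, path, CANOPUS_SCHEME_COLUMNS)
    back = read_canopus_summary(path)
    assert back["s1"].terms_by_scheme[NPC_PATHWAY] == [("Polyketides", 0.91), ("Alkaloids", 0.35)]
    assert back["s1"].source == CANOPUS


def test_mne_table_has_classyfire_only(tmp_path):
    path = tmp_path / "ClassyFireResults_Network.txt"
    path.write_text(
        "cluster index\tCF_superclass\tCF_superclass_score\n"
        "s9\tOrganoheterocyclic compounds\t0.77\n"
    )
    preds = read_mne_table(path)
    assert preds["s9"].source == MOLNETENHANCER
    assert preds["s9"].terms_by_scheme[CF_SUPERCLASS] == [("Organoheterocyclic compounds", 0.77)]
    assert NPC_PATHWAY not in preds["s9"].terms_by_scheme


def test_read_class_predictions_requires_a_source():
    with pytest.raises(EmptyInputError):
        read_class_predictions(None, None)


def test_prediction_dialect_error(tmp_path):
    path = tmp_path / "odd.tsv"
    path.write_text("weird\t(columns)\n1\t2\n")
    with pytest.raises(DialectError, match="cluster index"):
        read_canopus_summary(path)


def test_wide_score_table_dialect(tmp_path):
    path = tmp_path / "wide.tsv"
    path.write_text(
        "\tPolyketides\tTerpenoids\n"
        "Polyketide\t0.76\t0.05\n"
        "Terpene\t\t0.65\n"
    )
    table = read_wide_score_table(path, MIBIG_CLASS, NPC_PATHWAY, "genome_to_structure")
    assert table.score("Polyketide", "Polyketides") == 0.76
    assert table.score("Terpene", "Terpenoids") == 0.65
    assert table.score("Terpene", "Polyketides") == 0.0


def test_bundle_round_trip(paired_dataset, tmp_path):
    bundle, _truth = paired_dataset
    write_bundle(bundle, tmp_path)
    back = load_dataset(tmp_path)
    assert back.spectrum_masses == bundle.spectrum_masses
    assert back.spectrum_strains == bundle.spectrum_strains
    assert {g.gcf_id for g in back.gcf_records} == {g.gcf_id for g in bundle.gcf_records}
    orig = {g.gcf_id: g for g in bundle.gcf_records}
    for g in back.gcf_records:
        assert sorted(g.member_bgc_ids) == sorted(orig[g.gcf_id].member_bgc_ids)
        assert g.bigscape_class == orig[g.gcf_id].bigscape_class
    assert set(back.canopus) == set(bundle.canopus)
    for sid, pred in back.canopus.items():
        assert pred.terms_by_scheme == bundle.canopus[sid].terms_by_scheme
    assert {tuple(sorted(v)) for v in back.mf_membership.values()} == {
        tuple(sorted(v)) for v in bundle.mf_membership.values()
    }
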