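from pathlib import Path

import pytest

from classlink import SimConfig, build_all_tables, generate_entry_set, generate_paired_dataset
from classlink.ontology import (
    ANTISMASH_CLASS,
    CF_SUPERCLASS,
    MIBIG_CLASS,
    NPC_PATHWAY,
    ClassSet,
    ClassTerm,
)
from classlink.tables import CountMatrix, ScoreTableSet, build_score_table

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1234)


@pytest.fixture(scope="session")
def entry_set(sim_config):
    return generate_entry_set(sim_config)


@pytest.fixture(scope="session")
def reference_tables(entry_set):
    return build_all_tables(entry_set)


@pytest.fixture(scope="session")
def paired_dataset(sim_config):
    return generate_paired_dataset(sim_config)


@pytest.fixture()
def tiny_tables():
    """Hand-built two-table set with known scores."""
    cm1 = CountMatrix(MIBIG_CLASS, NPC_PATHWAY)
    cm1.counts[("Polyketide", "Polyketides")] = 548
    cm1.genome_marginals["Polyketide"] = 722
    cm1.structure_marginals["Polyketides"] = 600
    cm2 = CountMatrix(ANTISMASH_CLASS, CF_SUPERCLASS)
    cm2.counts[("indole", "Organoheterocyclic compounds")] = 39
    cm2.genome_marginals["indole"] = 50
    cm2.structure_marginals["Organoheterocyclic compounds"] = 80
    tset = ScoreTableSet()
    for cm in (cm1, cm2):
        tset.add(build_score_table(cm, "genome_to_structure"))
        tset.add(build_score_table(cm, "structure_to_genome"))
    return tset


def genome_set(*terms):
    cs = ClassSet("genome")
    for scheme, label in terms:
        cs.add(ClassTerm(scheme, label))
    return cs


def structure_set(*terms):
    cs = ClassSet("structure")
    for scheme, label in terms:
        cs.add(ClassTerm(scheme, label))
    return cs
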