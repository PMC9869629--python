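"""Seeded generators for reference entry sets and paired omics datasets.

The entry generator emulates a repository of class-annotated BGC–structure
pairs: each entry draws one biosynthetic class and then carries each
structure class with the probability given by an association matrix, so the
rebuilt score tables concentrate around that matrix.

The paired-dataset generator emulates one multi-strain study: GCFs and
spectra with strain presence patterns, CANOPUS/MolNetEnhancer-style class
predictions, and a list of planted true links.  Planted links co-occur in
the same strains and carry class pairs with high reference frequency.
Decoys are built in both failure modes — co-occurring with mismatched
classes, and class-matching without co-occurrence — so the two scores are
exercised as complements.  All randomness flows from one integer seed.

Spectra are metadata stubs (id, parent mass, strain occurrences, class
predictions); no fragmentation is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import CANOPUS, MOLNETENHANCER, ClassPrediction, GCFRecord
from .formats import DatasetBundle
from .ontology import (
    ANTISMASH_CLASS,
    CF_SUPERCLASS,
    MIBIG_CLASS,
    NPC_PATHWAY,
    ClassSet,
    ConfigError,
    ClassTerm,
)
from .tables import AnnotatedEntry

#: Default genome-class vocabulary (curated biosynthetic classes).
MIBIG_VOCAB = ("Polyketide", "NRP", "RiPP", "Terpene", "Saccharide", "Alkaloid", "Other")
#: Default structure-class vocabulary (NP-pathway terms), index-aligned with
#: MIBIG_VOCAB: position i is the "true" product pathway of genome class i.
NPC_PATHWAY_VOCAB = (
    "Polyketides",
    "Amino acids and Peptides",
    "Amino acids and Peptides",  # RiPPs are also peptidic
    "Terpenoids",
    "Carbohydrates",
    "Alkaloids",
    "Fatty acids",
)

ANTISMASH_FOR_MIBIG = {
    "Polyketide": ("T1PKS", "T2PKS"),
    "NRP": ("NRPS",),
    "RiPP": ("lanthipeptide",),
    "Terpene": ("terpene",),
    "Saccharide": ("oligosaccharide",),
    "Alkaloid": ("indole",),
    "Other": ("other",),
}

CF_SUPERCLASS_FOR_NPC = {
    "Polyketides": "Phenylpropanoids and polyketides",
    "Amino acids and Peptides": "Organic acids and derivatives",
    "Terpenoids": "Lipids and lipid-like molecules",
    "Carbohydrates": "Organic oxygen compounds",
    "Alkaloids": "Organoheterocyclic compounds",
    "Fatty acids": "Lipids and lipid-like molecules",
}

BIGSCAPE_FOR_MIBIG = {
    "Polyketide": "PKSI",
    "NRP": "NRPS",
    "RiPP": "RiPPs",
    "Terpene": "Terpene",
    "Saccharide": "Saccharides",
    "Alkaloid": "Others",
    "Other": "Others",
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    The defaults define the standard fixture: 2000 reference entries with a
    0.7 on-target / 0.05 background class association, and a paired dataset
    of 30 strains, 40 GCFs, 200 spectra and 10 planted links, noise-free.
    """

    seed: int
    n_entries: int = 2000
    association_strength: float = 0.7
    background_association: float = 0.05
    association: np.ndarray | None = None  # overrides the strength-built matrix
    genome_vocab: tuple[str, ...] = MIBIG_VOCAB
    structure_vocab: tuple[str, ...] = NPC_PATHWAY_VOCAB
    n_strains: int = 30
    n_gcfs: int = 40
    n_spectra: int = 200
    n_planted: int = 10
    n_cooccur_decoys: int = 15  # co-occur with a planted GCF, wrong class
    presence_noise: float = 0.0
    class_noise: float = 0.0
    fraction_unpredicted: float = 0.05  # spectra with no class prediction
    planted_links: list[tuple[int, int, int]] = field(default_factory=list)
    # (gcf index, spectrum index, genome-class index); auto-chosen when empty

    def association_matrix(self) -> np.ndarray:
        if self.association is not None:
            A = np.asarray(self.association, dtype=float)
            if A.shape != (len(self.genome_vocab), len(self.structure_vocab)):
                raise ConfigError("association matrix shape does not match vocabularies")
            return A
        if not self.genome_vocab or not self.structure_vocab:
            raise ConfigError("class vocabularies must be non-empty")
        n_g, n_s = len(self.genome_vocab), len(self.structure_vocab)
        A = np.full((n_g, n_s), self.background_association)
        for i in range(n_g):
            A[i, i % n_s] = self.association_strength
        return A

    def validate(self) -> None:
        for p in (
            self.association_strength,
            self.background_association,
            self.presence_noise,
            self.class_noise,
            self.fraction_unpredicted,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.n_planted + self.n_cooccur_decoys > min(self.n_gcfs, self.n_spectra):
            raise ConfigError("planted links + decoys exceed object counts")


def generate_entry_set(cfg: SimConfig) -> list[AnnotatedEntry]:
    """Draw class-annotated entries per the association matrix (seeded)."""
    cfg.validate()
    A = cfg.association_matrix()
    rng = np.random.default_rng([cfg.seed, 0])
    entries = []
    for i in range(cfg.n_entries):
        g_idx = int(rng.integers(len(cfg.genome_vocab)))
        b = cfg.genome_vocab[g_idx]
        genome = ClassSet("genome")
        genome.add(ClassTerm(MIBIG_CLASS, b))
        as_options = ANTISMASH_FOR_MIBIG.get(b, (b.lower(),))
        genome.add(ClassTerm(ANTISMASH_CLASS, as_options[int(rng.integers(len(as_options)))]))

        structure = ClassSet("structure")
        draws = rng.random(len(cfg.structure_vocab))
        for j, m in enumerate(cfg.structure_vocab):
            if draws[j] < A[g_idx, j]:
                structure.add(ClassTerm(NPC_PATHWAY, m))
                cf = CF_SUPERCLASS_FOR_NPC.get(m)
                if cf:
                    structure.add(ClassTerm(CF_SUPERCLASS, cf))
        entries.append(AnnotatedEntry(f"ENTRY{i:05d}", genome, structure))
    return entries


def _strain_subset(rng: np.random.Generator, n_strains: int, p: float) -> set[int]:
    """Random strain subset with 1 ≤ |S| ≤ n−1 (re-draw degenerate cases)."""
    while True:
        mask = rng.random(n_strains) < p
        k = int(mask.sum())
        if 0 < k < n_strains:
            return set(np.nonzero(mask)[0].tolist())


def generate_paired_dataset(
    cfg: SimConfig,
) -> tuple[DatasetBundle, list[tuple[str, str, str, str]]]:
    """Build one paired dataset plus its ground-truth link list.

    Returns the bundle and a list of (gcf_id, spectrum_id, genome class,
    structure class) for the planted links.  Deterministic given the seed.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    n_g = len(cfg.genome_vocab)
    strains = [f"STRAIN{i:02d}" for i in range(cfg.n_strains)]
    strain_maps = {s: [s, f"{s}.mzXML", f"{s}_genome"] for s in strains}

    gcf_ids = [f"FAM{i:03d}" for i in range(cfg.n_gcfs)]
    spec_ids = [str(100000 + i) for i in range(cfg.n_spectra)]

    planted = list(cfg.planted_links)
    if not planted:
        planted = [(k, k, k % n_g) for k in range(cfg.n_planted)]
    for g_i, s_i, c_i in planted:
        if g_i >= cfg.n_gcfs or s_i >= cfg.n_spectra or c_i >= n_g:
            raise ConfigError("planted link indices exceed object counts")

    planted_gcfs = {g_i: c_i for g_i, s_i, c_i in planted}
    planted_specs = {s_i: (g_i, c_i) for g_i, s_i, c_i in planted}

    # genome class per GCF and strain sets
    gcf_class_idx = [
        planted_gcfs.get(i, int(rng.integers(n_g))) for i in range(cfg.n_gcfs)
    ]
    shared_sets = {
        g_i: _strain_subset(rng, cfg.n_strains, 0.5) for g_i in planted_gcfs
    }
    gcf_strains = [
        shared_sets[i] if i in shared_sets else _strain_subset(rng, cfg.n_strains, 0.3)
        for i in range(cfg.n_gcfs)
    ]

    # spectrum strain sets: planted copy their GCF's set; the first
    # n_cooccur_decoys non-planted spectra copy a planted GCF's set too
    # (co-occurrence without class match); the rest are random.
    decoy_pool = [i for i in range(cfg.n_spectra) if i not in planted_specs]
    cooccur_decoys = set(decoy_pool[: cfg.n_cooccur_decoys])
    spec_strains: list[set[int]] = []
    decoy_host: dict[int, int] = {}
    planted_gcf_list = sorted(planted_gcfs)
    for i in range(cfg.n_spectra):
        if i in planted_specs:
            spec_strains.append(set(shared_sets[planted_specs[i][0]]))
        elif i in cooccur_decoys and planted_gcf_list:
            host = planted_gcf_list[i % len(planted_gcf_list)]
            decoy_host[i] = host
            spec_strains.append(set(shared_sets[host]))
        else:
            spec_strains.append(_strain_subset(rng, cfg.n_strains, 0.3))

    if cfg.presence_noise > 0:
        for i in range(cfg.n_spectra):
            flips = np.nonzero(rng.random(cfg.n_strains) < cfg.presence_noise)[0]
            spec_strains[i] ^= set(flips.tolist())

    # spectrum classes: planted get their pair's structure class; co-occurring
    # decoys get a class mismatching their host GCF; others random.
    spec_class_idx: list[int] = []
    for i in range(cfg.n_spectra):
        if i in planted_specs:
            m_idx = planted_specs[i][1] % len(cfg.structure_vocab)
        elif i in decoy_host:
            host_class = gcf_class_idx[decoy_host[i]]
            choices = [
                j
                for j in range(len(cfg.structure_vocab))
                if cfg.structure_vocab[j] != cfg.structure_vocab[host_class % len(cfg.structure_vocab)]
            ]
            m_idx = int(choices[int(rng.integers(len(choices)))])
        else:
            m_idx = int(rng.integers(len(cfg.structure_vocab)))
        if cfg.class_noise > 0 and rng.random() < cfg.class_noise:
            wrong = [j for j in range(len(cfg.structure_vocab)) if j != m_idx]
            m_idx = int(wrong[int(rng.integers(len(wrong)))])
        spec_class_idx.append(m_idx)

    # GCF records: one member BGC per occupied strain
    gcf_records = []
    for i, gcf_id in enumerate(gcf_ids):
        b = cfg.genome_vocab[gcf_class_idx[i]]
        members = [f"{strains[s]}_r{i:03d}.region001" for s in sorted(gcf_strains[i])]
        as_options = ANTISMASH_FOR_MIBIG.get(b, (b.lower(),))
        gcf_records.append(
            GCFRecord(
                gcf_id=gcf_id,
                member_bgc_ids=members,
                bigscape_class=BIGSCAPE_FOR_MIBIG.get(b, "Others"),
                antismash_classes_per_bgc={
                    m: [as_options[int(rng.integers(len(as_options)))]] for m in members
                },
            )
        )

    # spectrum masses and predictions
    unpredicted = set(
        np.nonzero(rng.random(cfg.n_spectra) < cfg.fraction_unpredicted)[0].tolist()
    ) - set(planted_specs)
    masses: dict[str, float] = {}
    canopus: dict[str, ClassPrediction] = {}
    mne: dict[str, ClassPrediction] = {}
    for i, spec_id in enumerate(spec_ids):
        planted_here = i in planted_specs
        mass = float(
            rng.uniform(200.0, 840.0) if planted_here else rng.uniform(150.0, 1500.0)
        )
        masses[spec_id] = round(mass, 3)
        if i in unpredicted:
            continue
        m = cfg.structure_vocab[spec_class_idx[i]]
        cf = CF_SUPERCLASS_FOR_NPC.get(m)
        if mass <= 850.0:
            pred = ClassPrediction(spec_id, CANOPUS)
            pred.terms_by_scheme[NPC_PATHWAY] = [(m, round(float(rng.uniform(0.6, 0.99)), 3))]
            if cf:
                pred.terms_by_scheme[CF_SUPERCLASS] = [
                    (cf, round(float(rng.uniform(0.6, 0.99)), 3))
                ]
            canopus[spec_id] = pred
        elif cf:
            pred = ClassPrediction(spec_id, MOLNETENHANCER)
            pred.terms_by_scheme[CF_SUPERCLASS] = [(cf, round(float(rng.uniform(0.5, 1.0)), 3))]
            mne[spec_id] = pred

    # molecular families: ~60% singletons, the rest grouped in pairs/triples;
    # planted spectra stay singletons so spectrum- and MF-level runs agree.
    mf_membership: dict[str, list[str]] = {}
    groupable = [i for i in range(cfg.n_spectra) if i not in planted_specs]
    rng.shuffle(groupable)
    n_grouped = int(0.4 * len(groupable))
    grouped, singles = groupable[:n_grouped], groupable[n_grouped:]
    comp = 1
    while grouped:
        size = int(rng.integers(2, 4))
        members, grouped = grouped[:size], grouped[size:]
        mf_membership[f"{comp}"] = [spec_ids[j] for j in sorted(members)]
        comp += 1
    for i in sorted(singles) + sorted(planted_specs):
        mf_membership[f"singleton_{spec_ids[i]}"] = [spec_ids[i]]

    bundle = DatasetBundle(
        gcf_records=gcf_records,
        spectrum_masses=masses,
        mf_membership=mf_membership,
        strain_maps=strain_maps,
        canopus=canopus,
        mne=mne,
        spectrum_strains={
            spec_ids[i]: {strains[s] for s in spec_strains[i]} for i in range(cfg.n_spectra)
        },
    )
    truth = [
        (
            gcf_ids[g_i],
            spec_ids[s_i],
            cfg.genome_vocab[c_i],
            cfg.structure_vocab[c_i % len(cfg.structure_vocab)],
        )
        for g_i, s_i, c_i in planted
    ]
    return bundle, truth
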