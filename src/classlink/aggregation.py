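"""Class assignment for GCFs, spectra and molecular families.

Genome side: a GCF inherits the MIBiG class translated from its BiG-SCAPE
family class, plus every harmonised antiSMASH class carried by at least
half of its member BGCs (inclusive).

Structure side: per-spectrum predictions come from CANOPUS (probabilistic,
used for parent masses up to 850 Da — the mass range fragmentation-tree
computation is practical for) or MolNetEnhancer (ClassyFire only, used for
heavier ions and for spectra CANOPUS did not cover).  CANOPUS terms are
thresholded at 0.5 (ClassyFire) / 0.33 (NPClassifier).  A molecular family
keeps the classes present in at least 20% of its member spectra.
All thresholds are inclusive (≥).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

from .ontology import (
    ANTISMASH_CLASS,
    MIBIG_CLASS,
    ClassScheme,
    ClassSet,
    OntologyConfig,
    harmonize_antismash_class,
    split_hybrid_label,
    translate_bigscape_class,
)

CANOPUS = "CANOPUS"
MOLNETENHANCER = "MOLNETENHANCER"

#: Parent-mass boundary (Da) up to which CANOPUS predictions are preferred.
CANOPUS_MASS_LIMIT = 850.0
CF_PROBABILITY_CUTOFF = 0.5
NPC_PROBABILITY_CUTOFF = 0.33
MF_CLASS_FRACTION = 0.20


class InvalidRecordError(ValueError):
    pass


class InvalidSourceError(ValueError):
    pass


class MissingPredictionError(KeyError):
    pass


@dataclass
class ClassPrediction:
    """Structure-based class terms (with optional probabilities) for one object."""

    object_id: str
    source: Literal["CANOPUS", "MOLNETENHANCER"]
    terms_by_scheme: dict[ClassScheme, list[tuple[str, float | None]]] = field(
        default_factory=dict
    )

    def to_class_set(self) -> ClassSet:
        cs = ClassSet("structure")
        for scheme in sorted(self.terms_by_scheme):
            for label, _p in self.terms_by_scheme[scheme]:
                for term in split_hybrid_label(label, scheme):
                    cs.add(term)
        return cs


@dataclass
class GCFRecord:
    """A gene cluster family: member BGCs plus their class annotations."""

    gcf_id: str
    member_bgc_ids: list[str]
    bigscape_class: str
    antismash_classes_per_bgc: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.member_bgc_ids:
            raise InvalidRecordError(f"GCF {self.gcf_id} has no member BGCs")


@dataclass
class MFRecord:
    """A molecular family: a connected component of similar MS/MS spectra."""

    mf_id: str
    member_spectrum_ids: list[str]

    def __post_init__(self) -> None:
        if not self.member_spectrum_ids:
            raise InvalidRecordError(f"MF {self.mf_id} has no member spectra")


def assign_gcf_classes(gcf: GCFRecord, config: OntologyConfig | None = None) -> ClassSet:
    """Genome-side class set of a GCF.

    MIBiG terms: the translated BiG-SCAPE class (hybrids kept grouped).
    antiSMASH terms: labels occurring in at least half of the member BGCs
    (count·2 ≥ n, inclusive), ordered by descending frequency then label.
    """
    config = config or OntologyConfig()
    cs = ClassSet("genome")
    mibig = translate_bigscape_class(gcf.bigscape_class, config.bigscape_to_mibig)
    cs.add_many(split_hybrid_label(mibig.label, MIBIG_CLASS, config.protected_tokens))

    n = len(gcf.member_bgc_ids)
    freq: dict[str, int] = {}
    for bgc in gcf.member_bgc_ids:
        labels = {
            t.label
            for raw in gcf.antismash_classes_per_bgc.get(bgc, [])
            for t in [harmonize_antismash_class(raw, "5", config.antismash_aliases)]
        }
        for label in labels:
            freq[label] = freq.get(label, 0) + 1
    kept = [label for label, c in freq.items() if 2 * c >= n]
    kept.sort(key=lambda label: (-freq[label], label))
    for label in kept:
        cs.add(harmonize_antismash_class(label, "5", config.antismash_aliases))
    return cs


def select_spectrum_classes(
    canopus: ClassPrediction | None,
    mne: ClassPrediction | None,
    parent_mass: float | None,
    mode: Literal["default", "canopus_only", "mne_only"] = "default",
    mass_limit: float = CANOPUS_MASS_LIMIT,
) -> ClassPrediction | None:
    """Pick the prediction source for one spectrum.

    Default: CANOPUS when the parent mass is at most ``mass_limit`` and a
    CANOPUS prediction exists; otherwise MolNetEnhancer when present;
    otherwise ``None``.  Single-source modes return only that source.
    """
    if mode == "canopus_only":
        return canopus
    if mode == "mne_only":
        return mne
    if canopus is not None and parent_mass is not None and parent_mass <= mass_limit:
        return canopus
    return mne


def apply_canopus_cutoffs(
    pred: ClassPrediction,
    cf_cutoff: float = CF_PROBABILITY_CUTOFF,
    npc_cutoff: float = NPC_PROBABILITY_CUTOFF,
) -> ClassPrediction:
    """Apply per-ontology probability cut-offs to a CANOPUS prediction.

    ClassyFire terms with probability ≥ ``cf_cutoff`` are kept in their
    incoming (priority) order; NPClassifier terms with probability ≥
    ``npc_cutoff`` are kept sorted by descending probability.  Terms without
    a probability are kept.
    """
    if pred.source != CANOPUS:
        raise InvalidSourceError(f"probability cut-offs apply to CANOPUS, not {pred.source}")
    out = ClassPrediction(pred.object_id, pred.source)
    for scheme, terms in pred.terms_by_scheme.items():
        if scheme.name.startswith("CF_"):
            kept = [(label, p) for label, p in terms if p is None or p >= cf_cutoff]
        else:
            kept = [(label, p) for label, p in terms if p is None or p >= npc_cutoff]
            kept.sort(key=lambda t: -(t[1] if t[1] is not None else 0.0))
        out.terms_by_scheme[scheme] = kept
    return out


def assign_mf_classes(
    mf: MFRecord,
    per_spectrum: Mapping[str, ClassPrediction | None],
    threshold: float = MF_CLASS_FRACTION,
) -> ClassSet:
    """Structure-side class set of a molecular family.

    Per scheme, a label is kept when it occurs in at least ``threshold`` of
    the member spectra (inclusive).  ClassyFire terms keep the first
    occurrence (priority) order over members; NPClassifier terms are ordered
    by occurrence count in the MF, descending.
    """
    n = len(mf.member_spectrum_ids)
    counts: dict[ClassScheme, dict[str, int]] = {}
    first_seen: dict[ClassScheme, list[str]] = {}
    for spec_id in mf.member_spectrum_ids:
        if spec_id not in per_spectrum:
            raise MissingPredictionError(f"MF {mf.mf_id}: no prediction entry for {spec_id}")
        pred = per_spectrum[spec_id]
        if pred is None:
            continue
        for scheme, terms in pred.terms_by_scheme.items():
            seen_here = set()
            for label, _p in terms:
                if label in seen_here:
                    continue
                seen_here.add(label)
                counts.setdefault(scheme, {})
                counts[scheme][label] = counts[scheme].get(label, 0) + 1
                order = first_seen.setdefault(scheme, [])
                if label not in order:
                    order.append(label)

    cs = ClassSet("structure")
    for scheme in sorted(counts):
        kept = [label for label in first_seen[scheme] if counts[scheme][label] / n >= threshold]
        if not scheme.name.startswith("CF_"):
            kept.sort(key=lambda label: (-counts[scheme][label], first_seen[scheme].index(label)))
        for label in kept:
            for term in split_hybrid_label(label, scheme):
                cs.add(term)
    return cs
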