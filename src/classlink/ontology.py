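"""Chemical-class ontology schemes, terms and label normalisation.

Genome-side ontologies (curated MIBiG biosynthetic classes, rule-based
antiSMASH cluster types) and structure-side ontologies (NPClassifier
pathway/superclass/class, ClassyFire kingdom→subclass) are represented by a
shared scheme/term model.  This module owns the normalisation steps every
other module relies on: splitting hybrid genome class labels (e.g.
``Polyketide-Terpene``), the special grouping of PKS–NRP hybrids at the
MIBiG class level, translating BiG-SCAPE family classes into MIBiG classes,
and harmonising antiSMASH labels from older tool versions to the v5
vocabulary.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

GENOME = "genome"
STRUCTURE = "structure"

HYBRID_DELIMITERS = ("-", "+")
#: Grouped term kept intact at the MIBiG class level: PKS-NRP hybrids are
#: counted as one class rather than split into components.
GROUPED_PKS_NRP = "Polyketide-NRP"


class InvalidLabelError(ValueError):
    """Raised for empty or malformed class labels."""


class ConfigError(ValueError):
    """Raised for inconsistent ontology/scoring configuration."""


@dataclass(frozen=True, order=True)
class ClassScheme:
    """One ontology level, e.g. the NPClassifier pathway level.

    ``level_rank`` orders levels within a scheme family (coarse → fine) and
    gives score tables a stable, deterministic ordering.
    """

    name: str
    side: str
    level_rank: int

    def __post_init__(self) -> None:
        if self.side not in (GENOME, STRUCTURE):
            raise ConfigError(f"scheme side must be genome|structure, got {self.side!r}")


# Genome-based levels
MIBIG_CLASS = ClassScheme("MIBIG_CLASS", GENOME, 0)
MIBIG_SUBCLASS = ClassScheme("MIBIG_SUBCLASS", GENOME, 1)
ANTISMASH_CLASS = ClassScheme("ANTISMASH_CLASS", GENOME, 2)

# Structure-based levels
NPC_PATHWAY = ClassScheme("NPC_PATHWAY", STRUCTURE, 0)
NPC_SUPERCLASS = ClassScheme("NPC_SUPERCLASS", STRUCTURE, 1)
NPC_CLASS = ClassScheme("NPC_CLASS", STRUCTURE, 2)
NPC_ISGLYCOSIDE = ClassScheme("NPC_ISGLYCOSIDE", STRUCTURE, 3)
CF_KINGDOM = ClassScheme("CF_KINGDOM", STRUCTURE, 4)
CF_SUPERCLASS = ClassScheme("CF_SUPERCLASS", STRUCTURE, 5)
CF_CLASS = ClassScheme("CF_CLASS", STRUCTURE, 6)
CF_SUBCLASS = ClassScheme("CF_SUBCLASS", STRUCTURE, 7)

SCHEMES: dict[str, ClassScheme] = {
    s.name: s
    for s in (
        MIBIG_CLASS,
        MIBIG_SUBCLASS,
        ANTISMASH_CLASS,
        NPC_PATHWAY,
        NPC_SUPERCLASS,
        NPC_CLASS,
        NPC_ISGLYCOSIDE,
        CF_KINGDOM,
        CF_SUPERCLASS,
        CF_CLASS,
        CF_SUBCLASS,
    )
}

#: Levels entering the scoring tables by default.  MIBIG_SUBCLASS and
#: NPC_ISGLYCOSIDE are representable but excluded: those levels cannot be
#: predicted from BGCs or MS/MS spectra, so no query ever carries them.
DEFAULT_GENOME_LEVELS: tuple[ClassScheme, ...] = (MIBIG_CLASS, ANTISMASH_CLASS)
DEFAULT_STRUCTURE_LEVELS: tuple[ClassScheme, ...] = (
    NPC_PATHWAY,
    NPC_SUPERCLASS,
    NPC_CLASS,
    CF_KINGDOM,
    CF_SUPERCLASS,
    CF_CLASS,
    CF_SUBCLASS,
)

#: BiG-SCAPE family classes → MIBiG biosynthetic classes (editable via config).
DEFAULT_BIGSCAPE_TO_MIBIG: dict[str, str] = {
    "PKSI": "Polyketide",
    "PKSother": "Polyketide",
    "PKS-NRP_Hybrids": "Polyketide-NRP",
    "NRPS": "NRP",
    "RiPPs": "RiPP",
    "Saccharides": "Saccharide",
    "Terpene": "Terpene",
    "Others": "Other",
}

#: antiSMASH pre-v5 rule names → v5 names (editable via config).  Labels not
#: listed here pass through unchanged.
DEFAULT_ANTISMASH_ALIASES: dict[str, str] = {
    "transatpks": "transAT-PKS",
    "otherks": "PKS-like",
    "lantipeptide": "lanthipeptide",
    "nucleoside": "nucleoside",
    "cf_saccharide": "saccharide",
    "cf_fatty_acid": "fatty_acid",
}

#: Atomic genome-side labels containing a hybrid delimiter; these must not be
#: split into components.
DEFAULT_PROTECTED_TOKENS: tuple[str, ...] = (
    "Polyketide-NRP",
    "transAT-PKS-like",
    "transAT-PKS",
    "NRPS-like",
    "PKS-like",
    "NAPAA",
    "RRE-containing",
    "arylpolyene",
)


@dataclass(frozen=True, order=True)
class ClassTerm:
    """A single canonical class term within one scheme."""

    scheme: ClassScheme
    label: str

    def __post_init__(self) -> None:
        if not self.label or self.label != self.label.strip():
            raise InvalidLabelError(f"bad class label {self.label!r} for {self.scheme.name}")


@dataclass
class ClassSet:
    """Ordered class terms per scheme, all on one side (genome or structure).

    Term order within a scheme is meaningful: it records the priority or
    occurrence order assigned upstream and is preserved in reports.
    """

    side: str
    terms_by_scheme: dict[ClassScheme, list[ClassTerm]] = field(default_factory=dict)

    def add(self, term: ClassTerm) -> None:
        if term.scheme.side != self.side:
            raise ConfigError(
                f"term {term.label!r} is {term.scheme.side}-side; ClassSet is {self.side}-side"
            )
        bucket = self.terms_by_scheme.setdefault(term.scheme, [])
        if term not in bucket:
            bucket.append(term)

    def add_many(self, terms: Iterable[ClassTerm]) -> None:
        for t in terms:
            self.add(t)

    def labels(self, scheme: ClassScheme) -> list[str]:
        return [t.label for t in self.terms_by_scheme.get(scheme, [])]

    def schemes(self) -> list[ClassScheme]:
        return sorted(self.terms_by_scheme)

    def is_empty(self, levels: Sequence[ClassScheme] | None = None) -> bool:
        """True when no terms exist at any of the given (default: all) levels."""
        pool = self.terms_by_scheme if levels is None else {
            s: self.terms_by_scheme.get(s, []) for s in levels
        }
        return not any(pool.values())


def _tokenize(raw: str, protected: Sequence[str]) -> list[str]:
    """Split on hybrid delimiters, keeping protected tokens whole."""
    tokens: list[str] = []
    i = 0
    n = len(raw)
    by_len = sorted(protected, key=len, reverse=True)
    while i < n:
        for tok in by_len:
            end = i + len(tok)
            if raw.startswith(tok, i) and (end == n or raw[end] in HYBRID_DELIMITERS):
                tokens.append(tok)
                i = end + 1  # skip delimiter
                break
        else:
            cut = min(
                (raw.find(d, i) for d in HYBRID_DELIMITERS if raw.find(d, i) != -1),
                default=n,
            )
            piece = raw[i:cut].strip()
            if piece:
                tokens.append(piece)
            i = cut + 1
    return tokens


def split_hybrid_label(
    raw: str,
    scheme: ClassScheme,
    protected_tokens: Sequence[str] = DEFAULT_PROTECTED_TOKENS,
) -> list[ClassTerm]:
    """Normalise one raw class label into canonical terms.

    Genome-side labels are split on ``-``/``+`` hybrid delimiters, except
    for atomic labels in ``protected_tokens``.  At the MIBiG class level an
    adjacent Polyketide/NRP component pair collapses into the grouped
    ``Polyketide-NRP`` term.  Structure-side labels are never split: terms
    like "Lipids and lipid-like molecules" contain literal hyphens.

    Duplicates are removed preserving first occurrence, so the operation is
    idempotent on its own output.
    """
    raw = raw.strip()
    if not raw:
        raise InvalidLabelError("empty class label")
    if scheme.side == STRUCTURE:
        return [ClassTerm(scheme, raw)]

    parts = _tokenize(raw, protected_tokens)
    if scheme is MIBIG_CLASS or scheme.name == "MIBIG_CLASS":
        grouped: list[str] = []
        i = 0
        while i < len(parts):
            pair = {parts[i]} | ({parts[i + 1]} if i + 1 < len(parts) else set())
            if pair == {"Polyketide", "NRP"}:
                grouped.append(GROUPED_PKS_NRP)
                i += 2
            else:
                grouped.append(parts[i])
                i += 1
        parts = grouped

    seen: list[str] = []
    for p in parts:
        if p not in seen:
            seen.append(p)
    return [ClassTerm(scheme, p) for p in seen]


def normalize_labels(
    labels: Iterable[str],
    scheme: ClassScheme,
    protected_tokens: Sequence[str] = DEFAULT_PROTECTED_TOKENS,
) -> list[ClassTerm]:
    """Normalise a list-valued class field, merging split results in order."""
    out: list[ClassTerm] = []
    for raw in labels:
        for term in split_hybrid_label(raw, scheme, protected_tokens):
            if term not in out:
                out.append(term)
    return out


def translate_bigscape_class(
    bigscape_label: str,
    mapping: Mapping[str, str] | None = None,
) -> ClassTerm:
    """Map a BiG-SCAPE family class to a MIBiG class term.

    Total: unknown (or empty) labels fall back to ``Other`` with a warning,
    so GCF annotation never fails on vocabulary drift.
    """
    mapping = DEFAULT_BIGSCAPE_TO_MIBIG if mapping is None else mapping
    label = bigscape_label.strip()
    if label in mapping:
        return ClassTerm(MIBIG_CLASS, mapping[label])
    logger.warning("unknown BiG-SCAPE class %r; falling back to 'Other'", bigscape_label)
    return ClassTerm(MIBIG_CLASS, "Other")


def harmonize_antismash_class(
    label: str,
    source_version: str = "5",
    aliases: Mapping[str, str] | None = None,
) -> ClassTerm:
    """Harmonise an antiSMASH cluster-type label to the v5 vocabulary.

    v5-style labels map to themselves.  Labels from older versions are looked
    up in the alias table; unknown labels pass through unchanged with a
    warning (graceful degradation beats failure).
    """
    aliases = DEFAULT_ANTISMASH_ALIASES if aliases is None else aliases
    label = label.strip()
    if not label:
        raise InvalidLabelError("empty antiSMASH class label")
    if label in aliases:
        return ClassTerm(ANTISMASH_CLASS, aliases[label])
    if label.lower() in aliases:
        return ClassTerm(ANTISMASH_CLASS, aliases[label.lower()])
    if not source_version.startswith("5"):
        logger.warning(
            "antiSMASH class %r (version %s) not in alias table; passing through",
            label,
            source_version,
        )
    return ClassTerm(ANTISMASH_CLASS, label)


@dataclass
class OntologyConfig:
    """Scoring-level inventory plus translation tables, user-overridable."""

    genome_levels: tuple[ClassScheme, ...] = DEFAULT_GENOME_LEVELS
    structure_levels: tuple[ClassScheme, ...] = DEFAULT_STRUCTURE_LEVELS
    bigscape_to_mibig: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BIGSCAPE_TO_MIBIG)
    )
    antismash_aliases: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ANTISMASH_ALIASES)
    )
    protected_tokens: tuple[str, ...] = DEFAULT_PROTECTED_TOKENS

    def level_pairs(self) -> list[tuple[ClassScheme, ClassScheme]]:
        return [(g, s) for g in self.genome_levels for s in self.structure_levels]

    def config_hash(self) -> str:
        payload = repr(
            (
                tuple(s.name for s in self.genome_levels),
                tuple(s.name for s in self.structure_levels),
                sorted(self.bigscape_to_mibig.items()),
                sorted(self.antismash_aliases.items()),
                self.protected_tokens,
            )
        ).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> OntologyConfig:
    """Load an :class:`OntologyConfig`, merging a YAML override into defaults.

    Recognised keys: ``genome_levels``, ``structure_levels`` (lists of scheme
    names), ``bigscape_to_mibig``, ``antismash_aliases`` (mappings, merged
    into the defaults), ``protected_tokens`` (list, replaces the default).
    """
    cfg = OntologyConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}

    def _levels(key: str, side: str, default: tuple[ClassScheme, ...]) -> tuple[ClassScheme, ...]:
        if key not in raw:
            return default
        out = []
        for name in raw[key]:
            if name not in SCHEMES:
                raise ConfigError(f"unknown scheme {name!r} in {key}")
            if SCHEMES[name].side != side:
                raise ConfigError(f"scheme {name!r} is not {side}-side")
            out.append(SCHEMES[name])
        return tuple(out)

    cfg.genome_levels = _levels("genome_levels", GENOME, cfg.genome_levels)
    cfg.structure_levels = _levels("structure_levels", STRUCTURE, cfg.structure_levels)
    cfg.bigscape_to_mibig.update(raw.get("bigscape_to_mibig", {}))
    cfg.antismash_aliases.update(raw.get("antismash_aliases", {}))
    if "protected_tokens" in raw:
        cfg.protected_tokens = tuple(raw["protected_tokens"])
    return cfg
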