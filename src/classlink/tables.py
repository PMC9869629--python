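"""Directional class-match score tables built from annotated BGC–structure pairs.

Each reference entry pairs one BGC with the structure(s) it encodes, both
sides carrying class terms per ontology level.  For a (genome level,
structure level) pair, co-occurrences are counted per entry (binary: an
entry exhibiting a (b, m) pair contributes 1 regardless of multiplicity) and
turned into relative frequencies in two directions:

* genome → structure: ``score(b, m) = N_bm / N_b`` — of the entries whose
  BGC carries genome class *b*, the fraction whose structure carries *m*;
* structure → genome: ``score(b, m) = N_mb / N_m`` — the converse.

With the default level inventory (2 genome × 7 structure levels) this yields
28 tables.  Scores are stored at full precision; rounding happens only in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .ontology import ClassScheme, ClassSet, ConfigError, OntologyConfig

Direction = Literal["genome_to_structure", "structure_to_genome"]
DIRECTIONS: tuple[Direction, Direction] = ("genome_to_structure", "structure_to_genome")

TableKey = tuple[str, str, str]  # (genome_level, structure_level, direction)


class EmptyInputError(ValueError):
    """Raised when an operation requires at least one entry."""


class IntegrityError(ValueError):
    """Raised when counts and marginals are mutually inconsistent."""


@dataclass
class AnnotatedEntry:
    """One reference BGC–structure pair with class labels per level."""

    entry_id: str
    genome_classes: ClassSet
    structure_classes: ClassSet

    def __post_init__(self) -> None:
        if self.genome_classes.side != "genome" or self.structure_classes.side != "structure":
            raise ConfigError(f"entry {self.entry_id}: class sets on wrong sides")


@dataclass
class CountMatrix:
    """Per-entry co-occurrence counts for one (genome, structure) level pair.

    ``counts[(b, m)]`` is the number of entries carrying both terms;
    ``genome_marginals[b]`` / ``structure_marginals[m]`` count entries
    carrying the term at all, regardless of the other side.
    """

    genome_level: ClassScheme
    structure_level: ClassScheme
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    genome_marginals: dict[str, int] = field(default_factory=dict)
    structure_marginals: dict[str, int] = field(default_factory=dict)


@dataclass
class ScoreTable:
    """Relative class-match frequencies for one level pair and direction."""

    genome_level: ClassScheme
    structure_level: ClassScheme
    direction: Direction
    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    marginals: dict[str, int] = field(default_factory=dict)

    @property
    def table_id(self) -> TableKey:
        return (self.genome_level.name, self.structure_level.name, self.direction)

    def score(self, b: str, m: str) -> float:
        """Score for a (genome term, structure term) pair; absent pairs are 0."""
        return self.scores.get((b, m), 0.0)


@dataclass
class ScoreTableSet:
    """All directional score tables plus build provenance."""

    tables: dict[TableKey, ScoreTable] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, table: ScoreTable) -> None:
        self.tables[table.table_id] = table

    def by_direction(self, direction: Direction) -> list[ScoreTable]:
        return [t for k, t in sorted(self.tables.items()) if k[2] == direction]

    def genome_levels(self, directions: Sequence[Direction] = DIRECTIONS) -> list[str]:
        return sorted({k[0] for k in self.tables if k[2] in directions})

    def structure_levels(self, directions: Sequence[Direction] = DIRECTIONS) -> list[str]:
        return sorted({k[1] for k in self.tables if k[2] in directions})


def count_class_links(
    entries: Iterable[AnnotatedEntry],
    genome_level: ClassScheme,
    structure_level: ClassScheme,
) -> CountMatrix:
    """Count entry-level class co-occurrences at one level pair.

    Each entry contributes at most 1 per distinct (b, m) pair and at most 1
    per marginal term.  Entries lacking terms on one side still count toward
    the other side's marginals.
    """
    if genome_level.side != "genome" or structure_level.side != "structure":
        raise ConfigError(
            f"level pair ({genome_level.name}, {structure_level.name}) has wrong sides"
        )
    cm = CountMatrix(genome_level, structure_level)
    for entry in entries:
        b_terms = sorted(set(entry.genome_classes.labels(genome_level)))
        m_terms = sorted(set(entry.structure_classes.labels(structure_level)))
        for b in b_terms:
            cm.genome_marginals[b] = cm.genome_marginals.get(b, 0) + 1
        for m in m_terms:
            cm.structure_marginals[m] = cm.structure_marginals.get(m, 0) + 1
        for b in b_terms:
            for m in m_terms:
                cm.counts[(b, m)] = cm.counts.get((b, m), 0) + 1
    return cm


def build_score_table(counts: CountMatrix, direction: Direction) -> ScoreTable:
    """Turn a count matrix into relative frequencies for one direction.

    Zero-count pairs are omitted (implicit score 0).  A nonzero count with a
    zero marginal is impossible for consistently built counts and raises.
    """
    if direction not in DIRECTIONS:
        raise ConfigError(f"unknown direction {direction!r}")
    marginals = (
        counts.genome_marginals if direction == "genome_to_structure" else counts.structure_marginals
    )
    table = ScoreTable(counts.genome_level, counts.structure_level, direction)
    for (b, m), n in counts.counts.items():
        if n == 0:
            continue
        denom = marginals.get(b if direction == "genome_to_structure" else m, 0)
        if denom <= 0:
            raise IntegrityError(
                f"pair ({b!r}, {m!r}) has count {n} but zero marginal in {direction}"
            )
        if n > denom:
            raise IntegrityError(f"pair ({b!r}, {m!r}) count {n} exceeds marginal {denom}")
        table.scores[(b, m)] = n / denom
        table.counts[(b, m)] = n
    table.marginals = dict(marginals)
    return table


def build_all_tables(
    entries: Sequence[AnnotatedEntry],
    config: OntologyConfig | None = None,
) -> ScoreTableSet:
    """Build every (level pair, direction) table declared by the config."""
    config = config or OntologyConfig()
    entries = list(entries)
    if not entries:
        raise EmptyInputError("cannot build score tables from zero entries")
    tset = ScoreTableSet(
        provenance={"n_entries": len(entries), "config_hash": config.config_hash()}
    )
    for g, s in config.level_pairs():
        cm = count_class_links(entries, g, s)
        for direction in DIRECTIONS:
            tset.add(build_score_table(cm, direction))
    return tset
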