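"""The class-match score: max relative frequency over all tables and term pairs.

Given the genome-side class set *B* of a BGC/GCF and the structure-side
class set *M* of a spectrum/molecular family, the score is

    max over tables T, b in B, m in M of T.score(b, m)

where tables are restricted to the requested direction(s).  A score of 0
means both sides carry classes but the classes never co-occur among the
reference entries; MISSING means one side carries no classes at any
in-scope level at all, which downstream filtering can exempt or discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ontology import SCHEMES, ClassSet, ConfigError
from .tables import ScoreTableSet, TableKey

DIRECTION_MODES = ("genome", "metabolome", "both")

_MODE_TO_DIRECTIONS = {
    "genome": ("genome_to_structure",),
    "metabolome": ("structure_to_genome",),
    "both": ("genome_to_structure", "structure_to_genome"),
}


@dataclass
class ScoreResult:
    """Outcome of one class-match scoring call.

    ``score`` is ``None`` for MISSING (no classes on one side); otherwise it
    equals ``all_matches[0][0]``.  ``all_matches`` holds every evaluated
    (score, b, m, table_id) combination, best first, with the deterministic
    tie-break (higher score, then table_id, then term pair).
    """

    score: float | None
    best_genome_term: str | None = None
    best_structure_term: str | None = None
    table_id: TableKey | None = None
    all_matches: list[tuple[float, str, str, TableKey]] = field(default_factory=list)

    @property
    def is_missing(self) -> bool:
        return self.score is None


MISSING = ScoreResult(score=None)


def npclassscore(
    B: ClassSet,
    M: ClassSet,
    tables: ScoreTableSet,
    direction_mode: str = "both",
) -> ScoreResult:
    """Score a genome-side class set against a structure-side class set.

    ``direction_mode`` selects which table set(s) to consult: ``genome``
    (relative to the genome-class totals), ``metabolome`` (relative to the
    structure-class totals), or ``both`` (default; the max of the two, the
    lenient retention used when a link may be approached from either side).
    """
    if direction_mode not in DIRECTION_MODES:
        raise ConfigError(f"direction_mode must be one of {DIRECTION_MODES}")
    if not tables.tables:
        raise ConfigError("empty score-table set")
    if B.side != "genome" or M.side != "structure":
        raise ConfigError("npclassscore expects (genome-side, structure-side) class sets")

    directions = _MODE_TO_DIRECTIONS[direction_mode]
    g_levels = tables.genome_levels(directions)
    s_levels = tables.structure_levels(directions)

    b_has = any(B.labels(SCHEMES[g]) for g in g_levels)
    m_has = any(M.labels(SCHEMES[s]) for s in s_levels)
    if not b_has or not m_has:
        return ScoreResult(score=None)

    matches: list[tuple[float, str, str, TableKey]] = []
    for key in sorted(tables.tables):
        if key[2] not in directions:
            continue
        table = tables.tables[key]
        b_labels = B.labels(table.genome_level)
        m_labels = M.labels(table.structure_level)
        for b in b_labels:
            for m in m_labels:
                matches.append((table.score(b, m), b, m, key))

    if not matches:
        # terms exist, but never at a level pair covered by a table
        return ScoreResult(score=0.0)
    matches.sort(key=lambda t: (-t[0], t[3], t[1], t[2]))
    best = matches[0]
    return ScoreResult(
        score=best[0],
        best_genome_term=best[1],
        best_structure_term=best[2],
        table_id=best[3],
        all_matches=matches,
    )
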