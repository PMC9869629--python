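"""Filter-and-rerank pipeline combining co-occurrence with class matching.

Candidate links come from standardised co-occurrence scoring (default
cut-off 2.5).  Each link is then scored by the class-match score; links
scoring below the class cut-off (default 0.25 — a class pair must account
for at least a quarter of its class's occurrences among the reference
entries) are discarded, with links lacking structure- or genome-side
classes (MISSING) optionally exempted.  Surviving links are re-ranked by
co-occurrence score within each GCF using competition ranking: tied links
share the smallest applicable rank ("1 (n)" = rank 1 shared with n others).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .aggregation import (
    apply_canopus_cutoffs,
    assign_gcf_classes,
    assign_mf_classes,
    select_spectrum_classes,
)
from .cooccurrence import (
    DEFAULT_WEIGHTS,
    CandidateLink,
    MetcalfWeights,
    PresenceMatrix,
    candidate_links,
)
from .formats import DatasetBundle
from .ontology import ClassSet, OntologyConfig
from .scoring import ScoreResult, npclassscore
from .tables import EmptyInputError, ScoreTableSet

DEFAULT_CLASS_CUTOFF = 0.25
DEFAULT_METCALF_CUTOFF = 2.5


def filter_links_by_class(
    links: Iterable[CandidateLink],
    class_cutoff: float = DEFAULT_CLASS_CUTOFF,
    filter_missing: bool = True,
) -> list[CandidateLink]:
    """Keep links whose class score ≥ ``class_cutoff`` (inclusive).

    MISSING scores (no classes on one side) are kept when
    ``filter_missing`` is off, mirroring the toggle for retaining spectra
    without any structure-based prediction.
    """
    kept = []
    for link in links:
        result = link.classscore
        if result is None or result.is_missing:
            if not filter_missing:
                kept.append(link)
        elif result.score >= class_cutoff:
            kept.append(link)
    return kept


def _link_sort_value(link: CandidateLink, key: str) -> tuple:
    if key == "metcalf":
        return (link.metcalf,)
    if key == "classscore_then_metcalf":
        cs = link.classscore.score if link.classscore and not link.classscore.is_missing else -1.0
        return (cs, link.metcalf)
    raise ValueError(f"unknown ranking key {key!r}")


def rank_links(
    links: Sequence[CandidateLink],
    key: Literal["metcalf", "classscore_then_metcalf"] = "metcalf",
    scope: Literal["gcf", "object"] = "gcf",
    stage: Literal["before", "after"] = "before",
) -> list[CandidateLink]:
    """Assign competition ranks in place (per GCF by default).

    rank = 1 + number of strictly better links in the same scope; ties share
    the rank, and the shared count (ties − 1) matches the "rank (n)"
    reporting convention.
    """
    groups: dict[str, list[CandidateLink]] = {}
    for link in links:
        group_id = link.gcf_id if scope == "gcf" else link.object_id
        groups.setdefault(group_id, []).append(link)
    for members in groups.values():
        values = [_link_sort_value(link, key) for link in members]
        for link, value in zip(members, values):
            better = sum(1 for other in values if other > value)
            ties = sum(1 for other in values if other == value) - 1
            if stage == "before":
                link.rank_before, link.shared_before = better + 1, ties
            else:
                link.rank_after, link.shared_after = better + 1, ties
    return list(links)


@dataclass
class ReductionSummary:
    """Per-GCF and aggregate link-count reduction after class filtering."""

    per_gcf: dict[str, tuple[int, int, float]]  # gcf -> (n_before, n_after, pct_decrease)
    mean_pct_decrease: float
    pct_decrease_of_mean: float
    mean_before: float
    mean_after: float
    histogram: pd.DataFrame  # bin edges with before/after counts


def percent_decrease(n_before: float, n_after: float) -> float:
    """100·(1 − after/before); callers round only at report time."""
    if n_before <= 0:
        raise ValueError("percent decrease undefined for n_before <= 0")
    return 100.0 * (1.0 - n_after / n_before)


def aggregate_percent_decreases(decreases: Sequence[float]) -> float:
    """Mean of per-dataset percentual decreases."""
    if not decreases:
        raise EmptyInputError("no decreases to aggregate")
    return float(sum(decreases)) / len(decreases)


def summarize_reduction(
    before: Mapping[str, int],
    after: Mapping[str, int],
    bin_size: int = 25,
) -> ReductionSummary:
    """Summarise links-per-GCF counts before vs after filtering.

    Reports both the mean of per-GCF percent decreases and the percent
    decrease of the mean links-per-GCF (these differ; both appear in
    reports).  GCFs with zero links before filtering are excluded from the
    percentage statistics.
    """
    per_gcf: dict[str, tuple[int, int, float]] = {}
    decreases = []
    for gcf, n_before in before.items():
        n_after = after.get(gcf, 0)
        if n_after > n_before:
            raise ValueError(f"GCF {gcf}: more links after filtering ({n_after} > {n_before})")
        if n_before > 0:
            pct = percent_decrease(n_before, n_after)
            decreases.append(pct)
            per_gcf[gcf] = (n_before, n_after, pct)

    mean_before = sum(before.values()) / len(before) if before else 0.0
    mean_after = sum(after.get(g, 0) for g in before) / len(before) if before else 0.0
    max_n = max(list(before.values()) + [0])
    edges = list(range(0, max_n + bin_size + 1, bin_size))
    hist_rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        hist_rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n_gcfs_before": sum(1 for v in before.values() if lo <= v < hi),
                "n_gcfs_after": sum(1 for g in before if lo <= after.get(g, 0) < hi),
            }
        )
    return ReductionSummary(
        per_gcf=per_gcf,
        mean_pct_decrease=aggregate_percent_decreases(decreases) if decreases else 0.0,
        pct_decrease_of_mean=(
            percent_decrease(mean_before, mean_after) if mean_before > 0 else 0.0
        ),
        mean_before=mean_before,
        mean_after=mean_after,
        histogram=pd.DataFrame(hist_rows),
    )


def links_per_gcf(links: Iterable[CandidateLink]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for link in links:
        counts[link.gcf_id] = counts.get(link.gcf_id, 0) + 1
    return counts


@dataclass
class ValidationReport:
    """Outcome of re-checking experimentally validated links."""

    rows: pd.DataFrame  # input rows plus a 'status' column
    n_scored: int
    n_passing_class_threshold: int
    retention_pct: float
    n_rank1_after: int
    n_rank1_before: int


def evaluate_validated_links(
    table: pd.DataFrame, class_cutoff: float = DEFAULT_CLASS_CUTOFF
) -> ValidationReport:
    """Classify validated-link rows and compute retention statistics.

    Statuses: ``retained`` (both ranks present), ``discarded_metcalf``
    (passed the class threshold but fell below the co-occurrence cut-off),
    ``discarded_classscore`` (class score below the cut-off), ``not_found``
    (spectrum absent from the dataset).  Retention is the fraction of
    scored rows passing the class threshold, reported as a whole percent.
    """
    if table.empty:
        raise EmptyInputError("no validated-link rows")
    statuses = []
    for row in table.itertuples(index=False):
        if pd.isna(row.npclassscore):
            statuses.append("not_found")
        elif row.npclassscore < class_cutoff or getattr(row, "discarded_classscore", False):
            statuses.append("discarded_classscore")
        elif getattr(row, "discarded_metcalf", False) or pd.isna(row.rank_before):
            statuses.append("discarded_metcalf")
        else:
            statuses.append("retained")
    rows = table.copy()
    rows["status"] = statuses

    scored = rows[rows["npclassscore"].notna()]
    n_passing = int((scored["npclassscore"] >= class_cutoff).sum())
    return ValidationReport(
        rows=rows,
        n_scored=len(scored),
        n_passing_class_threshold=n_passing,
        retention_pct=100.0 * n_passing / len(scored) if len(scored) else 0.0,
        n_rank1_after=int((rows["rank_after"] == 1).sum()),
        n_rank1_before=int((rows["rank_before"] == 1).sum()),
    )


def threshold_sweep(
    links: Sequence[CandidateLink],
    cutoffs: Sequence[float],
    filter_missing: bool = True,
    true_links: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Re-filter at each cut-off; one summary row per cut-off.

    When ``true_links`` (gcf_id, object_id pairs) is given, the number of
    retained true links per cut-off is reported alongside.
    """
    truth = set(true_links or [])
    before_counts = links_per_gcf(links)
    rows = []
    for cutoff in cutoffs:
        surviving = filter_links_by_class(links, cutoff, filter_missing)
        summary = summarize_reduction(before_counts, links_per_gcf(surviving))
        rows.append(
            {
                "cutoff": cutoff,
                "n_links": len(surviving),
                "mean_links_per_gcf": summary.mean_after,
                "mean_pct_decrease": summary.mean_pct_decrease,
                "pct_decrease_of_mean": summary.pct_decrease_of_mean,
                "retained_true_links": sum(
                    1 for link in surviving if (link.gcf_id, link.object_id) in truth
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end orchestration

@dataclass
class LinkingResult:
    """Full pipeline output: all candidates, the survivors, and the summary."""

    links_before: list[CandidateLink]
    links_after: list[CandidateLink]
    summary: ReductionSummary
    gcf_classes: dict[str, ClassSet] = field(default_factory=dict)
    object_classes: dict[str, ClassSet] = field(default_factory=dict)


def spectrum_class_sets(
    bundle: DatasetBundle,
    source_mode: Literal["default", "canopus_only", "mne_only"] = "default",
) -> dict[str, ClassSet | None]:
    """Per-spectrum structure-side class sets after source selection and
    probability cut-offs.  ``None`` marks spectra without any prediction."""
    out: dict[str, ClassSet | None] = {}
    for spec_id, mass in bundle.spectrum_masses.items():
        pred = select_spectrum_classes(
            bundle.canopus.get(spec_id), bundle.mne.get(spec_id), mass, source_mode
        )
        if pred is None:
            out[spec_id] = None
            continue
        if pred.source == "CANOPUS":
            pred = apply_canopus_cutoffs(pred)
        out[spec_id] = pred.to_class_set()
    return out


def run_linking(
    bundle: DatasetBundle,
    tables: ScoreTableSet,
    metcalf_cutoff: float = DEFAULT_METCALF_CUTOFF,
    class_cutoff: float = DEFAULT_CLASS_CUTOFF,
    filter_missing: bool = True,
    direction_mode: str = "both",
    object_level: Literal["spectrum", "mf"] = "spectrum",
    weights: MetcalfWeights = DEFAULT_WEIGHTS,
    config: OntologyConfig | None = None,
) -> LinkingResult:
    """Run the whole pipeline on one dataset bundle.

    Steps: build strain presence matrices for GCFs and spectra/MFs, emit
    co-occurrence candidates at ``metcalf_cutoff``, attach class sets and
    class scores, rank, filter at ``class_cutoff``, re-rank survivors.
    """
    config = config or OntologyConfig()
    strains = sorted(bundle.strain_maps)

    bgc_strain = bundle.bgc_strains()
    gcf_presence = {
        gcf.gcf_id: {bgc_strain[b] for b in gcf.member_bgc_ids if bgc_strain[b] is not None}
        for gcf in bundle.gcf_records
    }
    gcf_presence = {g: s for g, s in gcf_presence.items() if s}
    gcf_matrix = PresenceMatrix.from_mapping(strains, gcf_presence)

    per_spectrum_classes = spectrum_class_sets(bundle)
    if object_level == "spectrum":
        object_presence: dict[str, set[str]] = {
            s: set(st) for s, st in bundle.spectrum_strains.items() if st
        }
        object_classes: dict[str, ClassSet | None] = per_spectrum_classes
    else:
        from .aggregation import MFRecord  # local to avoid unused import at module load

        object_presence = {}
        object_classes = {}
        preds = {
            spec_id: (
                None
                if bundle.spectrum_masses.get(spec_id) is None
                else select_spectrum_classes(
                    bundle.canopus.get(spec_id),
                    bundle.mne.get(spec_id),
                    bundle.spectrum_masses.get(spec_id),
                )
            )
            for spec_id in bundle.spectrum_masses
        }
        preds = {
            k: (apply_canopus_cutoffs(v) if v is not None and v.source == "CANOPUS" else v)
            for k, v in preds.items()
        }
        for mf_id, members in bundle.mf_membership.items():
            strains_of_mf = set()
            for spec_id in members:
                strains_of_mf |= bundle.spectrum_strains.get(spec_id, set())
            if strains_of_mf:
                object_presence[mf_id] = strains_of_mf
            mf = MFRecord(mf_id, list(members))
            object_classes[mf_id] = assign_mf_classes(
                mf, {m: preds.get(m) for m in members}
            )

    spec_matrix = PresenceMatrix.from_mapping(strains, object_presence)
    links = candidate_links(gcf_matrix, spec_matrix, weights, metcalf_cutoff)

    gcf_classes = {
        gcf.gcf_id: assign_gcf_classes(gcf, config)
        for gcf in bundle.gcf_records
        if gcf.gcf_id in gcf_presence
    }
    for link in links:
        obj_classes = object_classes.get(link.object_id)
        link.classscore = (
            ScoreResult(score=None)
            if obj_classes is None
            else npclassscore(gcf_classes[link.gcf_id], obj_classes, tables, direction_mode)
        )

    rank_links(links, stage="before")
    survivors = filter_links_by_class(links, class_cutoff, filter_missing)
    rank_links(survivors, stage="after")

    summary = summarize_reduction(links_per_gcf(links), links_per_gcf(survivors))
    return LinkingResult(
        links_before=links,
        links_after=survivors,
        summary=summary,
        gcf_classes=gcf_classes,
        object_classes={k: v for k, v in object_classes.items() if v is not None},
    )


def links_to_frame(links: Sequence[CandidateLink]) -> pd.DataFrame:
    """Flatten links to the output-table layout."""
    rows = []
    for link in links:
        cs = link.classscore
        rows.append(
            {
                "gcf_id": link.gcf_id,
                "object_id": link.object_id,
                "metcalf": link.metcalf,
                "npclassscore": None if cs is None or cs.is_missing else cs.score,
                "best_genome_term": None if cs is None else cs.best_genome_term,
                "best_structure_term": None if cs is None else cs.best_structure_term,
                "table_id": None if cs is None or cs.table_id is None else "|".join(cs.table_id),
                "rank_before": link.rank_before,
                "shared_before": link.shared_before,
                "rank_after": link.rank_after,
                "shared_after": link.shared_after,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gcf_id",
            "object_id",
            "metcalf",
            "npclassscore",
            "best_genome_term",
            "best_structure_term",
            "table_id",
            "rank_before",
            "shared_before",
            "rank_after",
            "shared_after",
        ],
    )
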