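"""Readers and writers for every external file dialect.

Formats handled (all plain text):

* annotated reference entries — JSON (per-entry label lists per scheme) or a
  flat TSV (``entry_id  scheme  label``);
* score tables — one TSV per (level pair, direction) with columns
  ``genome_term  structure_term  count  marginal  score`` plus a JSON
  manifest, and a wide-matrix alternate dialect (rows = genome terms,
  columns = structure terms, cells = scores);
* BiG-SCAPE clustering TSVs (``BGC name`` / ``Family Number``, one file per
  class and cut-off);
* strain-mapping CSV (first column canonical strain id, rest aliases);
* MGF spectra (metadata only: SCANS/TITLE id and PEPMASS parent mass) via
  pyteomics;
* GNPS network tables (``cluster index`` / ``componentindex`` membership;
  ``cluster index`` / ``filename`` per-file occurrence);
* per-spectrum class predictions — CANOPUS summary TSV and the
  MolNetEnhancer ``ClassyFireResults_Network.txt`` table.

Column names drift across upstream tool versions, so every tabular reader
accepts a column-mapping override of its documented default header.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .aggregation import CANOPUS, MOLNETENHANCER, ClassPrediction, GCFRecord
from .ontology import (
    SCHEMES,
    ClassScheme,
    ClassSet,
    OntologyConfig,
    normalize_labels,
)
from .tables import (
    AnnotatedEntry,
    EmptyInputError,
    ScoreTable,
    ScoreTableSet,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


class DialectError(ParseError):
    pass


# ---------------------------------------------------------------------------
# annotated entries

def _entry_from_label_maps(
    entry_id: str,
    genome: Mapping[str, Sequence[str]],
    structure: Mapping[str, Sequence[str]],
    config: OntologyConfig,
) -> AnnotatedEntry:
    g = ClassSet("genome")
    s = ClassSet("structure")
    for scheme_name, labels in genome.items():
        if scheme_name not in SCHEMES:
            raise ParseError(f"entry {entry_id}: unknown scheme {scheme_name!r}")
        g.add_many(normalize_labels(labels, SCHEMES[scheme_name], config.protected_tokens))
    for scheme_name, labels in structure.items():
        if scheme_name not in SCHEMES:
            raise ParseError(f"entry {entry_id}: unknown scheme {scheme_name!r}")
        s.add_many(normalize_labels(labels, SCHEMES[scheme_name], config.protected_tokens))
    return AnnotatedEntry(entry_id, g, s)


def read_annotated_entries(
    path: str | Path, config: OntologyConfig | None = None
) -> list[AnnotatedEntry]:
    """Read reference entries from the JSON dialect or the flat TSV dialect.

    Entries lacking class terms on both sides are dropped with a warning.
    """
    config = config or OntologyConfig()
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        records = _read_entries_tsv(path)
    else:
        try:
            records = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not records:
        raise EmptyInputError(f"{path}: no entries")

    entries: list[AnnotatedEntry] = []
    for rec in records:
        try:
            entry = _entry_from_label_maps(
                rec["entry_id"],
                rec.get("genome_classes", {}),
                rec.get("structure_classes", {}),
                config,
            )
        except KeyError as exc:
            raise ParseError(f"{path}: entry record missing {exc}") from exc
        if entry.genome_classes.is_empty() and entry.structure_classes.is_empty():
            logger.warning("entry %s has no classes on either side; dropped", entry.entry_id)
            continue
        entries.append(entry)
    return entries


def _read_entries_tsv(path: Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"entry_id", "scheme", "label"}
    if not required.issubset(df.columns):
        raise DialectError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    records: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        rec = records.setdefault(
            row.entry_id, {"entry_id": row.entry_id, "genome_classes": {}, "structure_classes": {}}
        )
        if row.scheme not in SCHEMES:
            raise ParseError(f"{path}: entry {row.entry_id} has unknown scheme {row.scheme!r}")
        side = "genome_classes" if SCHEMES[row.scheme].side == "genome" else "structure_classes"
        rec[side].setdefault(row.scheme, []).append(row.label)
    return list(records.values())


def write_annotated_entries(entries: Iterable[AnnotatedEntry], path: str | Path) -> None:
    records = []
    for e in entries:
        records.append(
            {
                "entry_id": e.entry_id,
                "genome_classes": {
                    s.name: e.genome_classes.labels(s) for s in e.genome_classes.schemes()
                },
                "structure_classes": {
                    s.name: e.structure_classes.labels(s) for s in e.structure_classes.schemes()
                },
            }
        )
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


# ---------------------------------------------------------------------------
# score tables

def _table_filename(table: ScoreTable) -> str:
    g, s, d = table.table_id
    return f"{g}__{s}__{d}.tsv"


def write_score_tables(tables: ScoreTableSet, out_dir: str | Path) -> None:
    """One TSV per table plus ``manifest.json`` with provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    filenames = []
    for key in sorted(tables.tables):
        table = tables.tables[key]
        fname = _table_filename(table)
        filenames.append(fname)
        rows = []
        denom_key = 0 if table.direction == "genome_to_structure" else 1
        for (b, m) in sorted(table.scores):
            pair = (b, m)
            rows.append(
                {
                    "genome_term": b,
                    "structure_term": m,
                    "count": table.counts.get(pair, 0),
                    "marginal": table.marginals.get(pair[denom_key], 0),
                    "score": repr(table.scores[pair]),
                }
            )
        pd.DataFrame(
            rows, columns=["genome_term", "structure_term", "count", "marginal", "score"]
        ).to_csv(out_dir / fname, sep="\t", index=False)
    manifest = {"provenance": tables.provenance, "tables": filenames}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def read_score_tables(in_dir: str | Path) -> ScoreTableSet:
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise DialectError(f"{in_dir}: missing manifest.json")
    manifest = json.loads(manifest_path.read_text())
    tset = ScoreTableSet(provenance=manifest.get("provenance", {}))
    for fname in manifest["tables"]:
        stem = Path(fname).stem
        try:
            g_name, s_name, direction = stem.split("__")
        except ValueError as exc:
            raise DialectError(f"{fname}: expected GENOME__STRUCTURE__DIRECTION.tsv") from exc
        table = ScoreTable(SCHEMES[g_name], SCHEMES[s_name], direction)  # type: ignore[arg-type]
        df = pd.read_csv(in_dir / fname, sep="\t", dtype={"genome_term": str, "structure_term": str})
        denom_key = 0 if direction == "genome_to_structure" else 1
        for b, m, count, marginal, score in zip(
            df["genome_term"], df["structure_term"], df["count"], df["marginal"], df["score"]
        ):
            pair = (str(b), str(m))
            count, marginal = int(count), int(marginal)
            table.counts[pair] = count
            table.marginals[pair[denom_key]] = marginal
            # recompute from the integer pair so round-trips are bit-identical
            table.scores[pair] = count / marginal if marginal else float(score)
        tset.add(table)
    return tset


def read_wide_score_table(
    path: str | Path,
    genome_level: ClassScheme,
    structure_level: ClassScheme,
    direction: str,
) -> ScoreTable:
    """Alternate dialect: a wide matrix with genome terms as rows, structure
    terms as columns and relative-frequency scores as cells (the layout the
    published tables use).  Zero/empty cells are omitted from the table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    table = ScoreTable(genome_level, structure_level, direction)  # type: ignore[arg-type]
    for b, row in df.iterrows():
        for m, val in row.items():
            if pd.notna(val) and float(val) > 0:
                table.scores[(str(b), str(m))] = float(val)
    return table


# ---------------------------------------------------------------------------
# BiG-SCAPE clustering + antiSMASH sidecar

def read_bigscape_clustering(
    path: str | Path, columns: tuple[str, str] = ("BGC Name", "Family Number")
) -> dict[str, str]:
    """One clustering TSV (per class and cut-off) → {bgc_id: family_id}.

    Duplicate consistent rows deduplicate; conflicting family assignments
    for one BGC raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    bgc_col, fam_col = columns
    if bgc_col not in df.columns or fam_col not in df.columns:
        raise DialectError(
            f"{path}: expected columns {columns!r}, got {list(df.columns)}"
        )
    mapping: dict[str, str] = {}
    for bgc, fam in zip(df[bgc_col], df[fam_col]):
        bgc, fam = str(bgc), str(fam)
        if bgc in mapping and mapping[bgc] != fam:
            raise ParseError(f"{path}: BGC {bgc} assigned to families {mapping[bgc]} and {fam}")
        mapping[bgc] = fam
    return mapping


def read_antismash_classes(path: str | Path) -> dict[str, list[str]]:
    """Sidecar TSV ``bgc_id <tab> classes`` (semicolon-joined antiSMASH labels)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"bgc_id", "classes"}.issubset(df.columns):
        raise DialectError(f"{path}: expected columns ['bgc_id', 'classes']")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        labels = [] if pd.isna(row.classes) else [c for c in str(row.classes).split(";") if c]
        out[str(row.bgc_id)] = labels
    return out


def build_gcf_records(
    clusterings: Mapping[str, Mapping[str, str]],
    antismash_classes: Mapping[str, list[str]] | None = None,
) -> list[GCFRecord]:
    """Assemble GCF records from {bigscape_class: {bgc: family}} mappings."""
    antismash_classes = antismash_classes or {}
    members: dict[str, tuple[str, list[str]]] = {}
    for bigscape_class, mapping in clusterings.items():
        for bgc, fam in mapping.items():
            cls, bgcs = members.setdefault(fam, (bigscape_class, []))
            if cls != bigscape_class:
                raise ParseError(f"family {fam} appears under classes {cls} and {bigscape_class}")
            bgcs.append(bgc)
    records = []
    for fam in sorted(members):
        bigscape_class, bgcs = members[fam]
        bgcs = sorted(set(bgcs))
        records.append(
            GCFRecord(
                gcf_id=fam,
                member_bgc_ids=bgcs,
                bigscape_class=bigscape_class,
                antismash_classes_per_bgc={
                    b: antismash_classes.get(b, []) for b in bgcs
                },
            )
        )
    return records


def read_bigscape_dir(dir_path: str | Path) -> dict[str, dict[str, str]]:
    """Scan a directory of ``<class>_clustering_c*.tsv`` files."""
    dir_path = Path(dir_path)
    clusterings: dict[str, dict[str, str]] = {}
    for path in sorted(dir_path.glob("*_clustering_c*.tsv")):
        bigscape_class = path.name.split("_clustering_c")[0]
        clusterings[bigscape_class] = read_bigscape_clustering(path)
    if not clusterings:
        raise EmptyInputError(f"{dir_path}: no *_clustering_c*.tsv files")
    return clusterings


# ---------------------------------------------------------------------------
# strain mapping and alias resolution

def read_strain_mapping(path: str | Path) -> dict[str, list[str]]:
    """CSV, one row per strain: canonical id first, aliases after (no header)."""
    out: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            cells = [c.strip() for c in row if c.strip()]
            if not cells:
                continue
            out[cells[0]] = cells
    if not out:
        raise EmptyInputError(f"{path}: no strains")
    return out


def write_strain_mapping(strain_maps: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for canonical in strain_maps:
            writer.writerow(strain_maps[canonical])


def resolve_strain(name: str, strain_maps: Mapping[str, list[str]]) -> str | None:
    """Resolve a file/BGC name to a canonical strain id via alias matching.

    Exact alias match wins; otherwise the longest alias occurring as a
    substring of the name.  ``None`` when nothing matches.
    """
    alias_to_canonical: dict[str, str] = {}
    for canonical, aliases in strain_maps.items():
        for a in aliases:
            alias_to_canonical.setdefault(a, canonical)
    if name in alias_to_canonical:
        return alias_to_canonical[name]
    hits = [a for a in alias_to_canonical if a in name]
    if not hits:
        return None
    return alias_to_canonical[max(hits, key=len)]


# ---------------------------------------------------------------------------
# MGF + GNPS network tables

def read_mgf_masses(path: str | Path) -> dict[str, float]:
    """Spectrum id → parent mass (Da) from an MGF file.

    The id comes from SCANS, falling back to TITLE.  A spectrum without
    PEPMASS raises a parse error naming the scan.
    """
    masses: dict[str, float] = {}
    with _mgf.MGF(str(path), convert_arrays=0) as reader:
        for spectrum in reader:
            params = spectrum.get("params", {})
            spec_id = str(params.get("scans", params.get("title", ""))).strip()
            if not spec_id:
                raise ParseError(f"{path}: spectrum without SCANS or TITLE")
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ParseError(f"{path}: spectrum {spec_id} has no PEPMASS")
            masses[spec_id] = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
    return masses


def write_mgf_stub(spectrum_masses: Mapping[str, float], path: str | Path) -> None:
    """Write metadata-stub spectra (two dummy peaks) for testing/fixtures."""
    spectra = []
    for spec_id in spectrum_masses:
        mass = spectrum_masses[spec_id]
        spectra.append(
            {
                "m/z array": np.array([100.0, mass]),
                "intensity array": np.array([1.0, 1.0]),
                "params": {"title": spec_id, "scans": spec_id, "pepmass": mass},
            }
        )
    _mgf.write(spectra, str(path), file_mode="w")


def read_network_components(
    path: str | Path, columns: tuple[str, str] = ("cluster index", "componentindex")
) -> dict[str, list[str]]:
    """GNPS clusterinfosummary → {mf_id: [spectrum ids]}.

    Component index −1 is the GNPS singleton convention: each such spectrum
    becomes its own singleton MF named ``singleton_<id>``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    spec_col, comp_col = columns
    if spec_col not in df.columns or comp_col not in df.columns:
        raise DialectError(f"{path}: expected columns {columns!r}, got {list(df.columns)}")
    membership: dict[str, list[str]] = {}
    for spec_id, comp in zip(df[spec_col], df[comp_col]):
        spec_id, comp = str(spec_id), str(comp)
        if comp == "-1":
            membership[f"singleton_{spec_id}"] = [spec_id]
        else:
            membership.setdefault(comp, []).append(spec_id)
    return membership


def read_clusterinfo_strains(
    path: str | Path,
    strain_maps: Mapping[str, list[str]],
    columns: tuple[str, str] = ("cluster index", "filename"),
) -> dict[str, set[str]]:
    """GNPS clusterinfo (one row per spectrum occurrence per file) →
    {spectrum id: set of canonical strain ids}.  Filenames that resolve to no
    known strain are skipped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    spec_col, file_col = columns
    if spec_col not in df.columns or file_col not in df.columns:
        raise DialectError(f"{path}: expected columns {columns!r}, got {list(df.columns)}")
    out: dict[str, set[str]] = {}
    unresolved: set[str] = set()
    for spec_id, fname in zip(df[spec_col], df[file_col]):
        spec_id, fname = str(spec_id), str(fname)
        strain = resolve_strain(fname, strain_maps)
        if strain is None:
            unresolved.add(fname)
            continue
        out.setdefault(spec_id, set()).add(strain)
    for fname in sorted(unresolved):
        logger.warning("clusterinfo filename %r matches no strain alias", fname)
    return out


# ---------------------------------------------------------------------------
# class-prediction tables

#: Documented default header prefixes → schemes for the CANOPUS summary.
CANOPUS_SCHEME_COLUMNS: dict[str, str] = {
    "CF_kingdom": "CF_KINGDOM",
    "CF_superclass": "CF_SUPERCLASS",
    "CF_class": "CF_CLASS",
    "CF_subclass": "CF_SUBCLASS",
    "NPC_pathway": "NPC_PATHWAY",
    "NPC_superclass": "NPC_SUPERCLASS",
    "NPC_class": "NPC_CLASS",
}

MNE_SCHEME_COLUMNS: dict[str, str] = {
    "CF_kingdom": "CF_KINGDOM",
    "CF_superclass": "CF_SUPERCLASS",
    "CF_class": "CF_CLASS",
    "CF_subclass": "CF_SUBCLASS",
}


def _parse_prediction_row(
    row: Mapping[str, object],
    object_id: str,
    source: str,
    scheme_columns: Mapping[str, str],
) -> ClassPrediction:
    pred = ClassPrediction(object_id, source)  # type: ignore[arg-type]
    for col, scheme_name in scheme_columns.items():
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            continue
        labels = [t.strip() for t in str(raw).split(";") if t.strip()]
        raw_scores = row.get(f"{col}_score")
        probs: list[float | None]
        if raw_scores is None or (isinstance(raw_scores, float) and np.isnan(raw_scores)):
            probs = [None] * len(labels)
        else:
            probs = [float(x) for x in str(raw_scores).split(";") if str(x).strip() != ""]
            if len(probs) != len(labels):
                raise ParseError(
                    f"object {object_id}: {col} has {len(labels)} labels but "
                    f"{len(probs)} scores"
                )
        pred.terms_by_scheme[SCHEMES[scheme_name]] = list(zip(labels, probs))
    return pred


def read_canopus_summary(
    path: str | Path,
    id_column: str = "cluster index",
    scheme_columns: Mapping[str, str] | None = None,
) -> dict[str, ClassPrediction]:
    """CANOPUS per-spectrum summary TSV → {spectrum id: prediction}.

    Documented dialect: an id column plus, per ontology level, a term column
    (``;``-joined labels) and a ``<col>_score`` column (``;``-joined
    posterior probabilities).  Both the id column and the level columns can
    be remapped for other tool versions.
    """
    scheme_columns = dict(scheme_columns or CANOPUS_SCHEME_COLUMNS)
    df = pd.read_csv(path, sep="\t")
    if id_column not in df.columns:
        raise DialectError(
            f"{path}: expected id column {id_column!r} plus level columns "
            f"{sorted(scheme_columns)}; got {list(df.columns)}"
        )
    out: dict[str, ClassPrediction] = {}
    for _, row in df.iterrows():
        spec_id = str(row[id_column])
        out[spec_id] = _parse_prediction_row(row.to_dict(), spec_id, CANOPUS, scheme_columns)
    return out


def read_mne_table(
    path: str | Path,
    id_column: str = "cluster index",
    scheme_columns: Mapping[str, str] | None = None,
) -> dict[str, ClassPrediction]:
    """MolNetEnhancer ``ClassyFireResults_Network.txt`` → per-spectrum
    ClassyFire predictions (MolNetEnhancer provides no NPClassifier terms)."""
    scheme_columns = dict(scheme_columns or MNE_SCHEME_COLUMNS)
    df = pd.read_csv(path, sep="\t")
    if id_column not in df.columns:
        raise DialectError(
            f"{path}: expected id column {id_column!r} plus level columns "
            f"{sorted(scheme_columns)}; got {list(df.columns)}"
        )
    out: dict[str, ClassPrediction] = {}
    for _, row in df.iterrows():
        spec_id = str(row[id_column])
        out[spec_id] = _parse_prediction_row(row.to_dict(), spec_id, MOLNETENHANCER, scheme_columns)
    return out


def read_class_predictions(
    canopus_path: str | Path | None = None,
    mne_path: str | Path | None = None,
) -> tuple[dict[str, ClassPrediction], dict[str, ClassPrediction]]:
    """Read whichever prediction tables are given; at least one is required."""
    if canopus_path is None and mne_path is None:
        raise EmptyInputError("need a CANOPUS summary and/or a MolNetEnhancer table")
    canopus = read_canopus_summary(canopus_path) if canopus_path else {}
    mne = read_mne_table(mne_path) if mne_path else {}
    return canopus, mne


def write_prediction_table(
    predictions: Mapping[str, ClassPrediction],
    path: str | Path,
    scheme_columns: Mapping[str, str],
    id_column: str = "cluster index",
    with_scores: bool = True,
) -> None:
    rows = []
    for spec_id in predictions:
        pred = predictions[spec_id]
        row: dict[str, object] = {id_column: spec_id}
        for col, scheme_name in scheme_columns.items():
            terms = pred.terms_by_scheme.get(SCHEMES[scheme_name], [])
            row[col] = ";".join(label for label, _ in terms)
            if with_scores:
                row[f"{col}_score"] = ";".join(
                    "" if p is None else repr(p) for _, p in terms
                )
        rows.append(row)
    cols = [id_column]
    for col in scheme_columns:
        cols.append(col)
        if with_scores:
            cols.append(f"{col}_score")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# validated-links table

def read_validated_links(path: str | Path) -> pd.DataFrame:
    """Read a table of experimentally validated links with their scores/ranks.

    Dialect (tab-separated): ``name``, ``dataset``, ``rank_npclassscore``,
    ``rank_metcalf``, ``standardised_metcalf``, ``npclassscore``.  Rank cells
    are ``<rank>`` or ``<rank> (<n shared>)``; ``-`` marks a missing value
    and ``discarded`` marks a link removed by that scoring stage.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "name",
        "dataset",
        "rank_npclassscore",
        "rank_metcalf",
        "standardised_metcalf",
        "npclassscore",
    }
    if not required.issubset(df.columns):
        raise DialectError(f"{path}: expected columns {sorted(required)}")

    def parse_rank(cell: str) -> tuple[int | None, int, bool]:
        cell = (cell or "").strip()
        if cell in ("", "-"):
            return None, 0, False
        if cell.lower().startswith("discard"):
            return None, 0, True
        if "(" in cell:
            rank_part, shared_part = cell.split("(", 1)
            return int(rank_part.strip()), int(shared_part.strip(" )")), False
        return int(cell), 0, False

    out = pd.DataFrame({"name": df["name"], "dataset": df["dataset"]})
    parsed_after = df["rank_npclassscore"].fillna("-").map(parse_rank)
    parsed_before = df["rank_metcalf"].fillna("-").map(parse_rank)
    out["rank_after"] = [p[0] for p in parsed_after]
    out["shared_after"] = [p[1] for p in parsed_after]
    out["discarded_classscore"] = [p[2] for p in parsed_after]
    out["rank_before"] = [p[0] for p in parsed_before]
    out["shared_before"] = [p[1] for p in parsed_before]
    out["discarded_metcalf"] = [p[2] for p in parsed_before]
    out["metcalf"] = pd.to_numeric(df["standardised_metcalf"].replace("-", np.nan))
    out["npclassscore"] = pd.to_numeric(df["npclassscore"].replace("-", np.nan))
    return out


# ---------------------------------------------------------------------------
# dataset bundle

@dataclass
class DatasetBundle:
    """All inputs of one paired genome–metabolome dataset, in memory."""

    gcf_records: list[GCFRecord]
    spectrum_masses: dict[str, float]
    mf_membership: dict[str, list[str]]
    strain_maps: dict[str, list[str]]
    canopus: dict[str, ClassPrediction] = field(default_factory=dict)
    mne: dict[str, ClassPrediction] = field(default_factory=dict)
    spectrum_strains: dict[str, set[str]] = field(default_factory=dict)

    def bgc_strains(self) -> dict[str, str | None]:
        """Resolve each member BGC to its strain via the alias table."""
        out: dict[str, str | None] = {}
        for gcf in self.gcf_records:
            for bgc in gcf.member_bgc_ids:
                out[bgc] = resolve_strain(bgc, self.strain_maps)
        return out


BUNDLE_LAYOUT = {
    "strains": "strain_mappings.csv",
    "bigscape_dir": "bigscape",
    "antismash": "antismash_classes.tsv",
    "mgf": "spectra.mgf",
    "network": "clusterinfosummary.tsv",
    "clusterinfo": "clusterinfo.tsv",
    "canopus": "canopus_summary.tsv",
    "mne": "ClassyFireResults_Network.txt",
}


def load_dataset(root: str | Path) -> DatasetBundle:
    """Load a complete bundle from the on-disk layout ``write_bundle`` emits."""
    root = Path(root)
    strain_maps = read_strain_mapping(root / BUNDLE_LAYOUT["strains"])
    clusterings = read_bigscape_dir(root / BUNDLE_LAYOUT["bigscape_dir"])
    antismash = read_antismash_classes(root / BUNDLE_LAYOUT["antismash"])
    gcfs = build_gcf_records(clusterings, antismash)
    masses = read_mgf_masses(root / BUNDLE_LAYOUT["mgf"])
    mfs = read_network_components(root / BUNDLE_LAYOUT["network"])
    spectrum_strains = read_clusterinfo_strains(root / BUNDLE_LAYOUT["clusterinfo"], strain_maps)
    canopus_path = root / BUNDLE_LAYOUT["canopus"]
    mne_path = root / BUNDLE_LAYOUT["mne"]
    canopus, mne = read_class_predictions(
        canopus_path if canopus_path.exists() else None,
        mne_path if mne_path.exists() else None,
    )
    return DatasetBundle(
        gcf_records=gcfs,
        spectrum_masses=masses,
        mf_membership=mfs,
        strain_maps=strain_maps,
        canopus=canopus,
        mne=mne,
        spectrum_strains=spectrum_strains,
    )


def write_bundle(bundle: DatasetBundle, root: str | Path) -> None:
    """Write a bundle in the exact dialects :func:`load_dataset` reads."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    write_strain_mapping(bundle.strain_maps, root / BUNDLE_LAYOUT["strains"])

    bigscape_dir = root / BUNDLE_LAYOUT["bigscape_dir"]
    bigscape_dir.mkdir(exist_ok=True)
    by_class: dict[str, list[tuple[str, str]]] = {}
    antismash_rows = []
    for gcf in bundle.gcf_records:
        for bgc in gcf.member_bgc_ids:
            by_class.setdefault(gcf.bigscape_class, []).append((bgc, gcf.gcf_id))
            antismash_rows.append(
                {
                    "bgc_id": bgc,
                    "classes": ";".join(gcf.antismash_classes_per_bgc.get(bgc, [])),
                }
            )
    for bigscape_class in sorted(by_class):
        pd.DataFrame(
            sorted(by_class[bigscape_class]), columns=["BGC Name", "Family Number"]
        ).to_csv(bigscape_dir / f"{bigscape_class}_clustering_c0.30.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(antismash_rows, key=lambda r: r["bgc_id"])).to_csv(
        root / BUNDLE_LAYOUT["antismash"], sep="\t", index=False
    )

    write_mgf_stub(bundle.spectrum_masses, root / BUNDLE_LAYOUT["mgf"])

    net_rows = []
    for mf_id in bundle.mf_membership:
        for spec_id in bundle.mf_membership[mf_id]:
            comp = "-1" if mf_id.startswith("singleton_") else mf_id
            net_rows.append({"cluster index": spec_id, "componentindex": comp})
    pd.DataFrame(net_rows, columns=["cluster index", "componentindex"]).to_csv(
        root / BUNDLE_LAYOUT["network"], sep="\t", index=False
    )

    info_rows = []
    for spec_id in bundle.spectrum_strains:
        for strain in sorted(bundle.spectrum_strains[spec_id]):
            info_rows.append({"cluster index": spec_id, "filename": f"{strain}.mzXML"})
    pd.DataFrame(info_rows, columns=["cluster index", "filename"]).to_csv(
        root / BUNDLE_LAYOUT["clusterinfo"], sep="\t", index=False
    )

    if bundle.canopus:
        write_prediction_table(
            bundle.canopus, root / BUNDLE_LAYOUT["canopus"], CANOPUS_SCHEME_COLUMNS
        )
    if bundle.mne:
        write_prediction_table(bundle.mne, root / BUNDLE_LAYOUT["mne"], MNE_SCHEME_COLUMNS)
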