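# Methods

## Reference counting and score tables

The reference collection is a set of entries, each pairing one BGC with the
structure(s) it encodes, both sides carrying class labels per ontology
level. Counting is **per entry and binary**: an entry exhibiting the class
pair (b, m) contributes exactly 1 to `N_bm` regardless of how many of its
labels or compounds repeat the pair, because the unit of evidence is the
validated BGC–product relationship, not label multiplicity. An entry with
several products has their structure classes unioned before counting.
Marginals count entries carrying the term at all, so an entry with genome
classes but unclassified structures still inflates `N_b` (and thereby
deflates `N_bm / N_b`), which is the desired behaviour: unexplained entries
are evidence against a reliable match.

Directional scores are exact rationals `N_bm / N_b` (genome side) and
`N_mb / N_m` (metabolome side), stored at full float precision; 2-decimal
rounding happens only in reports. Zero-count pairs are omitted from the
sparse tables and read back as score 0. Serialisation keeps the integer
count and marginal per pair and recomputes the ratio on read, so
write→read round-trips are bit-identical.

### Level inventory

Default scoring levels: genome = {MIBiG class, antiSMASH class}; structure
= {NPClassifier pathway, superclass, class; ClassyFire kingdom, superclass,
class, subclass}. That is 14 level pairs × 2 directions = 28 tables. The
MIBiG subclass and NPClassifier is-glycoside levels are representable but
excluded from scoring by default because no genome- or spectrum-side
predictor emits them, so they can never match a query. The inventory is
configurable (`genome_levels` / `structure_levels` in the YAML config).

## Label normalisation

Genome-side labels are split on `-` and `+` hybrid delimiters
("Polyketide-Terpene" → two classes), with two refinements:

* at the MIBiG class level an adjacent Polyketide/NRP pair collapses into
  the single grouped class `Polyketide-NRP`, because PKS–NRPS hybrid
  machinery is a coherent biosynthetic category of its own, and splitting
  it would double-count entries under two only loosely applicable classes;
* a configurable protected-token list keeps atomic antiSMASH v5 labels
  containing hyphens (`transAT-PKS`, `NRPS-like`, `PKS-like`, …) intact.

Structure-side labels are never split: ClassyFire and NPClassifier terms
("Lipids and lipid-like molecules") legitimately contain hyphens and arrive
list-valued from their sources. Splitting is idempotent and
duplicate-free, preserving first occurrence.

BiG-SCAPE family classes are translated to MIBiG classes through a small
editable mapping (`PKSI`/`PKSother` → Polyketide, `NRPS` → NRP,
`PKS-NRP_Hybrids` → Polyketide-NRP, …); unknown labels fall back to `Other`
with a warning, so the translation is total. antiSMASH labels from pre-v5
tool versions are harmonised through an editable alias table
(`transatpks` → `transAT-PKS`, `otherks` → `PKS-like`,
`lantipeptide` → `lanthipeptide`); unknown labels pass through unchanged
with a warning rather than failing — an unrecognised class simply will not
match any table row.

## The class-match score

`npclassscore(B, M, tables, direction_mode)` returns the maximum table
score over all in-scope tables and all term pairs in `B × M`. The default
`direction_mode="both"` takes the max over both directional table sets:
the lenient retention policy appropriate for a *filter*, where a link
should survive if it is plausible from either the genome or the metabolome
viewpoint. `MISSING` (one side has no terms at any in-scope level) is kept
distinct from a genuine 0 (classes exist but never co-occur among
references); only the former is exempted when `filter_missing=False`. The
best-match report uses a deterministic tie-break: higher score, then
lexicographic table id, then lexicographic term pair. Term order inside
the class sets never affects the score value.

## Standardised co-occurrence score

The raw score is a weighted sum over the 2×2 strain contingency of a GCF
and a spectrum: default weights +10 (both present), −10 (GCF only), 0
(spectrum only), +1 (both absent) — rewarding co-presence and penalising a
cluster whose product is never seen. The published descriptions of this
family of scores do not pin down a standardisation, so this package defines
its contract explicitly: a z-score under the fixed-margins null in which
the number of strains carrying the GCF (n1) and the spectrum (n2) are held
fixed and the overlap o is hypergeometric(N, n1, n2). Since the raw score
is affine in o with slope
`a = w_both − w_gcf_only − w_spec_only + w_neither`,

```
z = sign(a) · (o − n1·n2/N) / sqrt( n1·n2·(N−n1)·(N−n2) / (N²·(N−1)) )
```

Degenerate margins (n1 or n2 ∈ {0, N}, or a = 0) return z = 0 rather than
NaN: a ubiquitous or absent object carries no co-occurrence information.
Consequences verified by tests: z is invariant to adding a constant to all
four weights and to positive scaling; swapping the two objects together
with the one-sided weights leaves z unchanged; under random placements
with fixed margins z has mean ≈ 0 and variance ≈ 1. Numeric parity with
other implementations of Metcalf-style scoring is *not* a goal; the
default cut-off 2.5 is interpreted against this null.

## Aggregation rules

* **GCF, genome side** — the translated BiG-SCAPE class plus every
  harmonised antiSMASH class occurring in at least half of the member BGCs
  (inclusive: `2·count ≥ n`), ordered by descending frequency then label.
* **Spectrum, structure side** — CANOPUS predictions are used for parent
  masses up to 850 Da inclusive (the mass range fragmentation-tree
  computation is practical for, matching a `--maxmz 850` run so that such a
  run is fully used); MolNetEnhancer otherwise and for spectra CANOPUS did
  not cover. MolNetEnhancer provides ClassyFire terms only. CANOPUS terms
  are thresholded at probability ≥ 0.5 (ClassyFire) and ≥ 0.33
  (NPClassifier); ClassyFire keeps its incoming order (the source file's
  priority order — the exact upstream priority system is not published, and
  order never affects the score, only reporting), NPClassifier is sorted by
  probability.
* **Molecular family** — a label is kept when it occurs in ≥ 20% of member
  spectra (inclusive); ClassyFire ordered by first occurrence across
  members, NPClassifier by occurrence count. MF terms carry no
  probabilities.

All thresholds are inclusive (≥), uniformly.

## Pipeline

Candidates at co-occurrence z ≥ 2.5 (per-dataset override supported) are
ranked per GCF by z using competition ranking (rank = 1 + number of
strictly better links; ties share the rank, and the "shared with n" count
is ties − 1). After class filtering at cut-off 0.25 (inclusive), survivors
are re-ranked by z among themselves — the class score acts as a filter, not
a ranking key, though a `classscore_then_metcalf` key is available. With
cut-off 0 and `filter_missing=False` the pipeline is the identity.

Reduction reports emit two statistics that genuinely differ: the mean of
per-GCF percent decreases, and the percent decrease of the mean
links-per-GCF. Percentages are rounded to whole percent only at report
time.

## Synthetic data

`SimConfig` defines the study conditions. The entry generator draws, per
entry, one genome class uniformly and then each structure class with the
probability in the association matrix (default: 0.7 for the index-aligned
"true" product pathway, 0.05 background); an aligned ClassyFire superclass
and a plausible antiSMASH class accompany each label. Defaults: 2000
entries — enough for rebuilt table scores to concentrate within a few
hundredths of the generating association.

The paired-dataset generator (defaults: 30 strains, 40 GCFs, 200 spectra,
10 planted links) plants links as GCF/spectrum pairs sharing an identical
strain subset (≈ half the strains) and carrying an index-aligned class
pair whose reference frequency (≈ 0.7) is well above the 0.25 cut-off.
Decoys come in both failure modes: spectra that copy a planted GCF's
strain set but carry a mismatching class (caught by the class filter), and
class-matching spectra with independent random presence (caught by the
co-occurrence cut-off). ~5% of non-planted spectra carry no prediction at
all, exercising the MISSING path. `presence_noise` flips presence cells;
`class_noise` replaces a spectrum's predicted class with a random wrong
one. All randomness flows from one integer seed through separate
`numpy` generator streams for entries and datasets; no global state.

What the generator does **not** emulate: real MS/MS fragmentation (spectra
are metadata stubs), correlated strain phylogeny (presence cells are
independent, whereas real BGCs are co-conserved across related strains —
the very effect that makes co-occurrence lists long), multi-class BGCs
beyond one antiSMASH label per member, disagreement between CANOPUS and
MolNetEnhancer on the same spectrum, and the skewed class abundances of
real repositories. Passing tests therefore demonstrate correctness of the
counting, scoring, filtering and ranking machinery under controlled
conditions — not field performance on real paired datasets.

## Numerical and degenerate-input choices

* Scores are exact integer ratios; no smoothing or pseudo-counts.
* A nonzero joint count with a zero marginal is an integrity error, not a
  silent division.
* Empty entry collections, empty GCFs/MFs, and empty validated-link tables
  raise; empty class sets flow through as MISSING.
* Presence matrices validate axis uniqueness and shape; candidate scoring
  requires an identical strain ordering on both matrices.
* Strain aliases resolve by exact match first, then longest-substring
  match; unresolvable filenames are skipped with a warning.

## Known limitations

* The reference tables shipped by a user drive everything; the package
  never classifies structures itself (no SMILES → ontology calls).
* Validated-link evaluation consumes a transcribed table of scores and
  ranks; reproducing the co-occurrence values behind such tables requires
  the original multi-strain datasets and is out of scope.
* Dataset-scale reduction figures depend on external repositories
  (antiSMASH/BiG-SCAPE/GNPS outputs for hundreds of strains) and are not
  recomputed here; the pipeline's reduction reporting is exercised on
  synthetic bundles instead.
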