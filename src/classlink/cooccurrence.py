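"""Standardised co-occurrence (Metcalf-style) scoring over strain presence/absence.

A gene cluster family (GCF) and a spectrum/molecular family are compared by
how their presence patterns across strains overlap.  The raw score is a
weighted sum of the four contingency cells (present in both, GCF only,
spectrum only, neither); by default co-presence is rewarded (+10),
GCF-without-spectrum penalised (−10), spectrum-only neutral and joint
absence mildly rewarded (+1).

The raw score is standardised under a fixed-margins null: with the number
of strains carrying the GCF (n1) and the spectrum (n2) held fixed, the
overlap o is hypergeometric(N, n1, n2).  Because the raw score is affine in
o, the z-score reduces to sign(a)·(o − E[o]) / sd(o) with
a = w_both − w_gcf_only − w_spec_only + w_neither,
E[o] = n1·n2/N and Var[o] = n1·n2·(N−n1)·(N−n2) / (N²·(N−1)).
Degenerate margins (n1 or n2 in {0, N}) carry no co-occurrence information
and score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .scoring import ScoreResult


class AlignmentError(ValueError):
    """Raised when presence vectors/matrices disagree on the strain index."""


class MetcalfWeights(NamedTuple):
    """Weights for the four contingency cells of the raw co-occurrence score."""

    both: float = 10.0
    gcf_only: float = -10.0
    spec_only: float = 0.0
    neither: float = 1.0


DEFAULT_WEIGHTS = MetcalfWeights()


@dataclass(frozen=True)
class Contingency:
    """2×2 presence/absence summary of a GCF and a spectrum across strains."""

    n_both: int
    n_gcf_only: int
    n_spec_only: int
    n_neither: int

    @property
    def n_strains(self) -> int:
        return self.n_both + self.n_gcf_only + self.n_spec_only + self.n_neither


@dataclass
class CandidateLink:
    """One GCF ↔ spectrum/MF pair with its scores and (tie-aware) ranks."""

    gcf_id: str
    object_id: str
    metcalf: float
    contingency: Contingency | None = None
    classscore: ScoreResult | None = None
    rank_before: int | None = None
    shared_before: int | None = None
    rank_after: int | None = None
    shared_after: int | None = None


@dataclass
class PresenceMatrix:
    """Boolean strains × objects occurrence matrix with labelled axes."""

    strain_ids: list[str]
    object_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise AlignmentError("duplicate strain ids")
        if len(set(self.object_ids)) != len(self.object_ids):
            raise AlignmentError("duplicate object ids")
        if self.values.shape != (len(self.strain_ids), len(self.object_ids)):
            raise AlignmentError(
                f"presence matrix shape {self.values.shape} does not match "
                f"{len(self.strain_ids)} strains × {len(self.object_ids)} objects"
            )

    @classmethod
    def from_mapping(
        cls, strain_ids: Sequence[str], presence: Mapping[str, set[str] | frozenset[str]]
    ) -> "PresenceMatrix":
        """Build from {object_id: set of strain ids}; unknown strains are ignored."""
        strain_ids = list(strain_ids)
        idx = {s: i for i, s in enumerate(strain_ids)}
        object_ids = list(presence)
        values = np.zeros((len(strain_ids), len(object_ids)), dtype=bool)
        for j, obj in enumerate(object_ids):
            for s in presence[obj]:
                if s in idx:
                    values[idx[s], j] = True
        return cls(strain_ids, object_ids, values)

    def column(self, object_id: str) -> np.ndarray:
        return self.values[:, self.object_ids.index(object_id)]


def contingency_counts(gcf_col: np.ndarray, spec_col: np.ndarray) -> Contingency:
    """Tabulate the four presence/absence cells over a shared strain index."""
    g = np.asarray(gcf_col, dtype=bool)
    s = np.asarray(spec_col, dtype=bool)
    if g.shape != s.shape or g.ndim != 1 or g.size < 1:
        raise AlignmentError(f"presence vectors misaligned: {g.shape} vs {s.shape}")
    return Contingency(
        n_both=int(np.sum(g & s)),
        n_gcf_only=int(np.sum(g & ~s)),
        n_spec_only=int(np.sum(~g & s)),
        n_neither=int(np.sum(~g & ~s)),
    )


def raw_metcalf(c: Contingency, weights: MetcalfWeights = DEFAULT_WEIGHTS) -> float:
    """Weighted sum of the contingency cells."""
    return (
        weights.both * c.n_both
        + weights.gcf_only * c.n_gcf_only
        + weights.spec_only * c.n_spec_only
        + weights.neither * c.n_neither
    )


def standardised_metcalf(c: Contingency, weights: MetcalfWeights = DEFAULT_WEIGHTS) -> float:
    """z-score of the raw score under the fixed-margins hypergeometric null."""
    N = c.n_strains
    n1 = c.n_both + c.n_gcf_only
    n2 = c.n_both + c.n_spec_only
    a = weights.both - weights.gcf_only - weights.spec_only + weights.neither
    if a == 0 or N < 2 or n1 in (0, N) or n2 in (0, N):
        return 0.0
    e_o = n1 * n2 / N
    var_o = n1 * n2 * (N - n1) * (N - n2) / (N**2 * (N - 1))
    return math.copysign(1.0, a) * (c.n_both - e_o) / math.sqrt(var_o)


def candidate_links(
    gcf_matrix: PresenceMatrix,
    spec_matrix: PresenceMatrix,
    weights: MetcalfWeights = DEFAULT_WEIGHTS,
    cutoff: float = 2.5,
) -> list[CandidateLink]:
    """All (GCF, spectrum/MF) pairs whose standardised score ≥ ``cutoff``.

    Vectorised over the full cross product; both matrices must share the
    same strain ordering.
    """
    if gcf_matrix.strain_ids != spec_matrix.strain_ids:
        raise AlignmentError("presence matrices do not share a strain index")
    N = len(gcf_matrix.strain_ids)
    if N == 0:
        raise AlignmentError("no shared strains")

    G = gcf_matrix.values.astype(np.int64)
    S = spec_matrix.values.astype(np.int64)
    n1 = G.sum(axis=0)  # per GCF
    n2 = S.sum(axis=0)  # per spectrum
    overlap = G.T @ S  # GCFs × spectra

    a = weights.both - weights.gcf_only - weights.spec_only + weights.neither
    e_o = np.outer(n1, n2) / N
    var_o = np.outer(n1 * (N - n1), n2 * (N - n2)) / (N**2 * (N - 1)) if N > 1 else np.zeros_like(e_o)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.sign(a) * (overlap - e_o) / np.sqrt(var_o)
    z = np.where((var_o > 0) & (a != 0), z, 0.0)

    links: list[CandidateLink] = []
    for i, j in zip(*np.nonzero(z >= cutoff)):
        c = Contingency(
            n_both=int(overlap[i, j]),
            n_gcf_only=int(n1[i] - overlap[i, j]),
            n_spec_only=int(n2[j] - overlap[i, j]),
            n_neither=int(N - n1[i] - n2[j] + overlap[i, j]),
        )
        links.append(
            CandidateLink(
                gcf_id=gcf_matrix.object_ids[i],
                object_id=spec_matrix.object_ids[j],
                metcalf=float(z[i, j]),
                contingency=c,
            )
        )
    return links
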