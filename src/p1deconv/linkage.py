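"""Co-transduction linkage mathematics.

Generalized transduction by phage P1 packages ~100 kb of donor genome; a
locus at distance *d* from a selected marker is co-inherited (here:
co-replaced by donor sequence) with probability

    f(d) = (1 - d/L)^3        for 0 <= d < L, else 0

with *L* the transducing-segment length (Wu's formula).  This module exposes
the curve itself, nearest-marker search on a circular genome, genome-wide
gene<->marker linkage tables, library coverage profiling and the probability
of separating two nearby mutations in one transduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .genome import (
    GeneFeature,
    GenomeMap,
    MarkerInsertion,
    MarkerLibrary,
)

__all__ = [
    "LinkageModel",
    "LinkageRecord",
    "CoverageSummary",
    "wu_frequency",
    "nearest_markers",
    "gene_linkage_table",
    "coverage_summary",
    "separation_probability",
    "round_half_up_percent",
]

DEFAULT_FRAGMENT_LENGTH = 100_000


@dataclass(frozen=True)
class LinkageModel:
    """Transduction linkage model parameterised by fragment length L (bp)."""

    fragment_length_L: int = DEFAULT_FRAGMENT_LENGTH

    def __post_init__(self) -> None:
        if self.fragment_length_L <= 0:
            raise ValueError(f"fragment length must be positive, got {self.fragment_length_L}")


@dataclass(frozen=True)
class LinkageRecord:
    """Predicted linkage of one locus to one marker."""

    locus_id: str
    marker_allele: str
    distance_bp: float
    frequency: float
    uncovered: bool = False  # frequency == 0 (locus beyond the fragment length)


@dataclass(frozen=True)
class CoverageSummary:
    """Worst-case linkage coverage of a marker library."""

    max_gap_bp: float
    worst_position_bp: float
    min_frequency: float
    gaps: tuple = field(default=(), repr=False)  # (left_allele, right_allele, gap_bp, midpoint_freq)


def wu_frequency(distance_bp: float, model: LinkageModel | None = None) -> float:
    """Predicted co-transduction frequency at distance ``distance_bp``.

    Returns ``(1 - d/L)**3`` for ``0 <= d < L`` and 0 beyond; distances may be
    half-integral (midpoint reference points).
    """
    if model is None:
        model = LinkageModel()
    if distance_bp < 0:
        raise ValueError(f"distance must be non-negative, got {distance_bp}")
    L = model.fragment_length_L
    if distance_bp >= L:
        return 0.0
    return (1.0 - distance_bp / L) ** 3


def round_half_up_percent(p: float) -> int:
    """Round a probability to an integer percent, halves up (17.5 -> 18)."""
    return int(math.floor(100.0 * p + 0.5))


def nearest_markers(
    pos_bp: float, library: MarkerLibrary, k: int = 1
) -> list[tuple[MarkerInsertion, float]]:
    """The ``k`` markers nearest ``pos_bp``, with their distances, ascending.

    Distances follow each marker's reference rule (interval midpoint for
    intergenic insertions, nearer edge for deletion-replacements) and use
    circular geometry.  Ties break by lower left coordinate, then allele id.
    """
    if len(library) == 0:
        raise ValueError("empty marker library")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(
        ((m, m.distance_to(pos_bp, library.genome)) for m in library),
        key=lambda md: (md[1], md[0].left_bp, md[0].allele_id),
    )
    return ranked[:k]


def gene_linkage_table(
    genes: Sequence[GeneFeature],
    library: MarkerLibrary,
    model: LinkageModel | None = None,
    k: int = 1,
) -> list[LinkageRecord]:
    """Per-gene k-nearest-marker linkage records (from gene midpoints).

    Rows whose predicted frequency is 0 (gene farther than L from every
    retained marker) are kept and flagged ``uncovered`` rather than dropped.
    """
    if model is None:
        model = LinkageModel()
    records = []
    for gene in genes:
        for marker, d in nearest_markers(gene.midpoint, library, k=min(k, len(library))):
            f = wu_frequency(d, model)
            records.append(
                LinkageRecord(gene.gene_id, marker.allele_id, d, f, uncovered=(f == 0.0))
            )
    return records


def write_linkage_table(records: Sequence[LinkageRecord], path: str | Path) -> None:
    """Write linkage records as TSV with both full-precision and percent columns."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tmarker_allele\tdistance_bp\tpredicted_freq\tfreq_percent\n")
        for r in records:
            fh.write(
                f"{r.locus_id}\t{r.marker_allele}\t{round(r.distance_bp)}\t"
                f"{r.frequency:.6f}\t{round_half_up_percent(r.frequency)}\n"
            )


def coverage_summary(
    library: MarkerLibrary, model: LinkageModel | None = None
) -> CoverageSummary:
    """Worst-case co-transduction frequency over the whole genome.

    On a circular genome with markers at their reference points, the minimum
    of ``wu(distance to nearest marker)`` is attained at the midpoint of the
    widest inter-marker gap, so the scan over gap midpoints is exact — no
    position sampling is needed.
    """
    if model is None:
        model = LinkageModel()
    if len(library) == 0:
        raise ValueError("empty marker library")
    genome = library.genome
    refs = library.reference_points()
    markers = list(library)
    n = len(refs)
    if n == 1:
        gap = float(genome.length_bp)
        a = markers[0]
        mid = (refs[0] + gap / 2 - 1) % genome.length_bp + 1
        f = wu_frequency(gap / 2, model)
        return CoverageSummary(gap, mid, f, ((a.allele_id, a.allele_id, gap, f),))
    gaps = []
    for i in range(n):
        j = (i + 1) % n
        gap = (refs[j] - refs[i]) % genome.length_bp
        if not genome.circular and j == 0:
            continue
        f = wu_frequency(gap / 2, model)
        gaps.append((markers[i].allele_id, markers[j].allele_id, gap, f))
    worst = max(gaps, key=lambda g: g[2])
    i_worst = gaps.index(worst)
    mid = (refs[i_worst] + worst[2] / 2 - 1) % genome.length_bp + 1
    return CoverageSummary(worst[2], mid, worst[3], tuple(gaps))


def separation_probability(
    d_near_bp: float, d_far_bp: float, model: LinkageModel | None = None
) -> float:
    """Probability one transduction separates two same-side mutations.

    For two mutations in the same inter-marker interval at distances
    ``d_near <= d_far`` from the marker, replacement is nested: whenever the
    far locus is replaced the near one is too.  The separation event —
    near replaced, far retained — therefore has probability
    ``wu(d_near) - wu(d_far)``.
    """
    if model is None:
        model = LinkageModel()
    if d_near_bp < 0:
        raise ValueError(f"distances must be non-negative, got {d_near_bp}")
    if d_near_bp > d_far_bp:
        raise ValueError(
            f"d_near ({d_near_bp}) > d_far ({d_far_bp}): swap the arguments so the "
            "nearer mutation comes first"
        )
    return wu_frequency(d_near_bp, model) - wu_frequency(d_far_bp, model)
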