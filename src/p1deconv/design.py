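"""Design new marker libraries at a target spacing inside intergenic regions.

A deconvolution library wants a selectable cassette roughly every half
fragment-length so that no locus falls below the minimum useful linkage, but
each insertion must land between genes so that no coding sequence is
disrupted.  The placement algorithm is grid-and-snap: ideal sites on a
regular grid, each snapped to the nearest intergenic point, followed by a
coverage audit of the snapped layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .genome import GeneFeature, GenomeMap, MarkerInsertion, MarkerLibrary
from .linkage import LinkageModel, coverage_summary, wu_frequency

__all__ = [
    "IntergenicRegion",
    "DesignSpec",
    "PlacementReport",
    "ValidationReport",
    "classify_intergenic_regions",
    "place_markers",
    "orientation_summary",
    "validate_library",
]

ORIENTATIONS = ("convergent", "codirectional", "divergent")


@dataclass(frozen=True)
class IntergenicRegion:
    """A gap between two gene blocks on the circular genome.

    ``end_bp`` may be numerically smaller than ``start_bp`` for the single
    wraparound region crossing the origin; ``span_bp`` accounts for that.
    Orientation comes from the flanking strands: (+,-) convergent,
    (-,+) divergent, same-strand codirectional.
    """

    start_bp: int
    end_bp: int
    left_gene: str
    right_gene: str
    orientation: str
    wraps: bool = False

    def span(self, genome: GenomeMap) -> int:
        if self.wraps:
            return genome.length_bp - self.start_bp + 1 + self.end_bp
        return self.end_bp - self.start_bp + 1

    def contains(self, pos: float, genome: GenomeMap) -> bool:
        if self.wraps:
            return pos >= self.start_bp or pos <= self.end_bp
        return self.start_bp <= pos <= self.end_bp


@dataclass(frozen=True)
class DesignSpec:
    """Target spacing and minimum acceptable linkage for a new library."""

    target_spacing_bp: int = 50_000
    min_frequency: float = 0.35
    model: LinkageModel = field(default_factory=LinkageModel)

    def __post_init__(self) -> None:
        if self.target_spacing_bp >= self.model.fragment_length_L:
            raise ValueError(
                f"target spacing {self.target_spacing_bp} must be below the fragment "
                f"length {self.model.fragment_length_L}, or coverage is impossible"
            )


@dataclass
class PlacementEntry:
    ideal_pos: int
    snapped_pos: int | None
    region_orientation: str | None
    shift_bp: int | None
    status: str  # placed | unplaceable


@dataclass
class PlacementReport:
    entries: list[PlacementEntry]
    violations: list[tuple[str, str, float, float]]  # (left, right, gap_bp, midpoint_freq)

    @property
    def n_placed(self) -> int:
        return sum(1 for e in self.entries if e.status == "placed")


@dataclass
class ValidationReport:
    passed: bool
    min_frequency: float
    floor: float
    failing_gaps: list[tuple[str, str, float, float]]


def _merge_gene_blocks(genes: Sequence[GeneFeature]) -> list[tuple[int, int, str, str, str]]:
    """Merge overlapping/abutting genes into blocks (start, end, id, left_strand, right_strand).

    A block's flanking strands are those of its outermost genes; its id joins
    the member ids for reporting.
    """
    if not genes:
        return []
    ordered = sorted(genes, key=lambda g: (g.start_bp, g.end_bp))
    blocks = []
    cur = [ordered[0]]
    for g in ordered[1:]:
        if g.start_bp <= max(x.end_bp for x in cur):
            cur.append(g)
        else:
            blocks.append(cur)
            cur = [g]
    blocks.append(cur)
    out = []
    for blk in blocks:
        start = min(g.start_bp for g in blk)
        end = max(g.end_bp for g in blk)
        first = min(blk, key=lambda g: g.start_bp)
        last = max(blk, key=lambda g: g.end_bp)
        bid = "+".join(g.gene_id for g in blk)
        out.append((start, end, bid, first.strand, last.strand))
    return out


def _orientation(left_strand: str, right_strand: str) -> str:
    if left_strand == "+" and right_strand == "-":
        return "convergent"
    if left_strand == "-" and right_strand == "+":
        return "divergent"
    return "codirectional"


def classify_intergenic_regions(
    genes: Sequence[GeneFeature], genome: GenomeMap
) -> list[IntergenicRegion]:
    """Extract all intergenic regions and classify them by flanking orientation.

    Overlapping genes are merged into blocks first; the regions (including
    the wraparound region on a circular genome) tile everything between
    blocks.  Zero-length regions between abutting blocks are omitted.  With
    no genes at all the whole genome is one region of undefined orientation.
    """
    blocks = _merge_gene_blocks(genes)
    if not blocks:
        return [
            IntergenicRegion(1, genome.length_bp, "(none)", "(none)", "undefined")
        ]
    regions = []
    n = len(blocks)
    for i in range(n):
        start_i, end_i, id_i, _, strand_right_of_left = blocks[i]
        j = (i + 1) % n
        start_j, _, id_j, strand_left_of_right, _ = blocks[j]
        # region between end of block i and start of block j
        r_start = end_i + 1
        r_end = start_j - 1
        wraps = j == 0
        if not genome.circular and wraps:
            # linear genome: emit leading/trailing ends separately
            if end_i < genome.length_bp:
                regions.append(
                    IntergenicRegion(end_i + 1, genome.length_bp, id_i, "(end)",
                                     "undefined")
                )
            if blocks[0][0] > 1:
                regions.append(
                    IntergenicRegion(1, blocks[0][0] - 1, "(start)", blocks[0][2],
                                     "undefined")
                )
            continue
        if wraps:
            if r_end < 1:
                r_end += genome.length_bp
            if r_start > genome.length_bp:
                r_start -= genome.length_bp
            span = (start_j - 1 - end_i) % genome.length_bp
            if span == 0:
                continue
            wraps_flag = r_start > r_end
            regions.append(
                IntergenicRegion(r_start, r_end, id_i, id_j,
                                 _orientation(strand_right_of_left, strand_left_of_right),
                                 wraps=wraps_flag)
            )
        else:
            if r_start > r_end:
                continue  # abutting or overlapping blocks: no region
            regions.append(
                IntergenicRegion(r_start, r_end, id_i, id_j,
                                 _orientation(strand_right_of_left, strand_left_of_right))
            )
    return regions


def _region_points(region: IntergenicRegion, genome: GenomeMap) -> list[tuple[int, int]]:
    """Linear segments [(lo, hi)] covered by a region in genome coordinates."""
    if region.wraps:
        return [(region.start_bp, genome.length_bp), (1, region.end_bp)]
    return [(region.start_bp, region.end_bp)]


def _snap(ideal: int, regions: Sequence[IntergenicRegion], genome: GenomeMap
          ) -> tuple[int, IntergenicRegion] | None:
    """Nearest intergenic point to ``ideal`` (circular); ties -> lower coordinate."""
    best: tuple[float, int, IntergenicRegion] | None = None
    from .genome import circular_distance

    for region in regions:
        for lo, hi in _region_points(region, genome):
            # candidate: clamp of ideal into [lo, hi], plus wraparound check
            if lo <= ideal <= hi:
                cand = ideal
            elif ideal < lo:
                cand = lo if circular_distance(ideal, lo, genome) <= circular_distance(ideal, hi, genome) else hi
            else:
                cand = hi if circular_distance(ideal, hi, genome) <= circular_distance(ideal, lo, genome) else lo
            d = circular_distance(ideal, cand, genome)
            key = (d, cand)
            if best is None or key < (best[0], best[1]):
                best = (d, cand, region)
    if best is None:
        return None
    return best[1], best[2]


def place_markers(
    regions: Sequence[IntergenicRegion],
    spec: DesignSpec,
    genome: GenomeMap,
    allele_prefix: str = "d",
) -> tuple[MarkerLibrary, PlacementReport]:
    """Grid-and-snap placement of a new intergenic marker library.

    Ideal sites sit at ``i * target_spacing`` around the circle; each is
    snapped to the nearest point inside any intergenic region (smallest
    shift, ties to the lower coordinate).  Sites with no intergenic point
    within half a fragment length are reported unplaceable, not raised.
    After snapping, each adjacent gap whose midpoint frequency falls below
    ``spec.min_frequency`` is listed as a coverage violation.
    Deterministic for fixed input.
    """
    L = spec.model.fragment_length_L
    n_sites = max(1, round(genome.length_bp / spec.target_spacing_bp))
    entries = []
    placed: list[MarkerInsertion] = []
    seen_pos: set[int] = set()
    from .genome import circular_distance

    for i in range(n_sites):
        ideal = (i * spec.target_spacing_bp) % genome.length_bp
        if ideal == 0:
            ideal = genome.length_bp
        snapped = _snap(ideal, regions, genome)
        if snapped is None:
            entries.append(PlacementEntry(ideal, None, None, None, "unplaceable"))
            continue
        pos, region = snapped
        shift = circular_distance(ideal, pos, genome)
        if shift > L / 2:
            entries.append(PlacementEntry(ideal, None, None, None, "unplaceable"))
            continue
        if pos in seen_pos:  # two grid points snapped to the same spot
            entries.append(PlacementEntry(ideal, pos, region.orientation, round(shift), "duplicate"))
            continue
        seen_pos.add(pos)
        entries.append(PlacementEntry(ideal, pos, region.orientation, round(shift), "placed"))
        right = pos + 1 if pos < genome.length_bp else pos
        left = pos if pos < genome.length_bp else pos - 1
        placed.append(
            MarkerInsertion(f"{allele_prefix}-{len(placed) + 1}", f"proposed-{len(placed) + 1}",
                            left, right, "intergenic-insertion")
        )
    library = MarkerLibrary(genome, placed)
    violations = []
    if len(library) > 0:
        cov = coverage_summary(library, spec.model)
        for left_a, right_a, gap, f in cov.gaps:
            if f < spec.min_frequency:
                violations.append((left_a, right_a, gap, f))
    report = PlacementReport(entries, violations)
    return library, report


def orientation_summary(
    library: MarkerLibrary, regions: Sequence[IntergenicRegion]
) -> dict[str, float]:
    """Fraction of markers per intergenic orientation class.

    Every marker must fall inside some region; a marker inside a gene block
    is a consistency error.
    """
    if len(library) == 0:
        raise ValueError("empty marker library")
    counts = {o: 0 for o in ORIENTATIONS}
    g = library.genome
    for m in library:
        # the cassette sits between left_bp and right_bp; it is intergenic if
        # either flank of the insertion point lies in a region
        region = next(
            (r for r in regions
             if r.contains(m.left_bp, g) or r.contains(m.right_bp, g)), None
        )
        if region is None:
            raise ValueError(
                f"marker {m.allele_id} at {m.midpoint} lies inside a gene block"
            )
        if region.orientation in counts:
            counts[region.orientation] += 1
        else:
            counts.setdefault(region.orientation, 0)
            counts[region.orientation] += 1
    total = sum(counts.values())
    return {o: c / total for o, c in counts.items()}


def validate_library(
    library: MarkerLibrary, spec: DesignSpec, genome: GenomeMap | None = None
) -> ValidationReport:
    """Audit a library against the minimum-linkage floor.

    PASS iff the worst-case (largest-gap midpoint) co-transduction frequency
    is at least ``spec.min_frequency``; all failing gaps are listed.
    """
    cov = coverage_summary(library, spec.model)
    failing = [g for g in cov.gaps if g[3] < spec.min_frequency]
    return ValidationReport(
        passed=cov.min_frequency >= spec.min_frequency,
        min_frequency=cov.min_frequency,
        floor=spec.min_frequency,
        failing_gaps=failing,
    )


def write_placement_report(report: PlacementReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("ideal_pos\tsnapped_pos\tregion_orientation\tshift_bp\tstatus\n")
        for e in report.entries:
            fh.write(
                f"{e.ideal_pos}\t{e.snapped_pos if e.snapped_pos is not None else '.'}\t"
                f"{e.region_orientation or '.'}\t"
                f"{e.shift_bp if e.shift_bp is not None else '.'}\t{e.status}\n"
            )
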