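"""Circular-genome coordinate model and readers/writers for the formats the tool touches.

Everything downstream works in 1-based inclusive coordinates on a single
circular chromosome (the *E. coli* K-12 convention).  The three input kinds
are a marker-insertion table (TSV), a gene annotation (GFF3 or a minimal
4-column TSV) and candidate mutations (VCF 4.x).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomeMap",
    "GeneFeature",
    "MarkerInsertion",
    "MarkerLibrary",
    "CandidateVariant",
    "CoordinateError",
    "FormatError",
    "DEFAULT_GENOME_LENGTH",
    "circular_distance",
    "signed_circular_offset",
    "load_marker_table",
    "write_marker_table",
    "load_gene_features",
    "load_variants",
    "load_packaged_library",
]

#: Length of the E. coli K-12 MG1655 chromosome (U00096.3), the default host.
DEFAULT_GENOME_LENGTH = 4_641_652

MARKER_KINDS = ("intergenic-insertion", "gene-replacement")


class CoordinateError(ValueError):
    """A position falls outside the genome or violates coordinate invariants."""


class FormatError(ValueError):
    """An input file does not conform to the expected dialect."""


@dataclass(frozen=True)
class GenomeMap:
    """A single circular (or linear) chromosome identified by name and length."""

    name: str = "chromosome"
    length_bp: int = DEFAULT_GENOME_LENGTH
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise CoordinateError(f"genome length must be positive, got {self.length_bp}")

    def check(self, pos: float, what: str = "position") -> float:
        if not (1 <= pos <= self.length_bp):
            raise CoordinateError(
                f"{what} {pos} outside genome '{self.name}' [1, {self.length_bp}]"
            )
        return pos


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene; the linkage reference point is its midpoint."""

    gene_id: str
    start_bp: int
    end_bp: int
    strand: str

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise FormatError(f"gene {self.gene_id}: coordinates are 1-based, got start {self.start_bp}")
        if self.start_bp > self.end_bp:
            raise FormatError(f"gene {self.gene_id}: start {self.start_bp} > end {self.end_bp}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start_bp + self.end_bp) / 2


@dataclass(frozen=True)
class MarkerInsertion:
    """A selectable cassette in the genome.

    The distance reference depends on ``kind``: an intergenic insertion sits
    between ``left_bp`` and ``right_bp`` and is referenced by their midpoint;
    a gene deletion-replacement spans an interval and distances are taken from
    whichever edge is nearer the query locus.
    """

    allele_id: str
    strain_id: str
    left_bp: int
    right_bp: int
    kind: str = "intergenic-insertion"

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise FormatError(f"marker {self.allele_id}: unknown kind {self.kind!r}")
        if not (1 <= self.left_bp <= self.right_bp):
            raise FormatError(
                f"marker {self.allele_id}: invalid interval {self.left_bp}-{self.right_bp}"
            )

    @property
    def midpoint(self) -> float:
        return (self.left_bp + self.right_bp) / 2

    def distance_to(self, pos: float, genome: GenomeMap) -> float:
        """Circular distance from ``pos`` under this marker's reference rule."""
        if self.kind == "gene-replacement":
            return min(
                circular_distance(pos, self.left_bp, genome),
                circular_distance(pos, self.right_bp, genome),
            )
        return circular_distance(pos, self.midpoint, genome)


@dataclass
class MarkerLibrary:
    """Ordered library of marker insertions on one genome.

    Markers are kept sorted by ``left_bp``; on a circular genome the successor
    of the last marker wraps to the first.
    """

    genome: GenomeMap
    markers: list[MarkerInsertion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.markers = sorted(self.markers, key=lambda m: m.left_bp)
        seen: set[str] = set()
        for m in self.markers:
            if m.allele_id in seen:
                raise FormatError(f"duplicate allele_id {m.allele_id!r}")
            seen.add(m.allele_id)
            if m.right_bp > self.genome.length_bp:
                raise CoordinateError(
                    f"marker {m.allele_id} right edge {m.right_bp} beyond genome "
                    f"length {self.genome.length_bp}"
                )

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, allele_id: str) -> MarkerInsertion:
        for m in self.markers:
            if m.allele_id == allele_id:
                return m
        raise KeyError(allele_id)

    def reference_points(self) -> list[float]:
        return [m.midpoint for m in self.markers]


@dataclass(frozen=True)
class CandidateVariant:
    """A sequenced candidate mutation (one per ALT allele of a VCF record)."""

    variant_id: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    var_class: str  # SNV | insertion | deletion

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"variant {self.variant_id}: REF equals ALT")


def circular_distance(a: float, b: float, genome: GenomeMap) -> float:
    """Shortest distance between two positions on the genome (bp).

    On a circular genome this is ``min(|a-b|, L - |a-b|)``; on a linear one it
    is plain ``|a-b|``.  Symmetric by construction.
    """
    genome.check(a, "position a")
    genome.check(b, "position b")
    d = abs(a - b)
    if genome.circular:
        return min(d, genome.length_bp - d)
    return d


def signed_circular_offset(pos: float, origin: float, genome: GenomeMap) -> float:
    """Signed offset of ``pos`` relative to ``origin`` in (-L/2, L/2].

    Positive means clockwise (increasing coordinate) of the origin.  Used by
    the transduction simulator to decide which side of a marker a locus lies.
    """
    genome.check(pos, "position")
    genome.check(origin, "origin")
    L = genome.length_bp
    off = (pos - origin) % L
    if off > L / 2:
        off -= L
    return off


# ---------------------------------------------------------------------------
# marker table TSV

_MARKER_COLUMNS = ["allele_id", "strain_id", "left_bp", "right_bp", "kind"]


def load_marker_table(path: str | Path, genome: GenomeMap) -> MarkerLibrary:
    """Read a marker-insertion library from TSV.

    Expected header: ``allele_id  strain_id  left_bp  right_bp  kind``.
    Rows are re-sorted by left coordinate; errors name the offending row.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty marker table")
    header = lines[0].rstrip("\n").split("\t")
    if header != _MARKER_COLUMNS:
        raise FormatError(
            f"{path}: bad header {header!r}, expected {_MARKER_COLUMNS!r}"
        )
    markers = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        allele_id, strain_id, left_s, right_s, kind = (p.strip() for p in parts)
        try:
            left, right = int(left_s), int(right_s)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-integer coordinate {left_s!r}/{right_s!r}"
            ) from None
        try:
            markers.append(MarkerInsertion(allele_id, strain_id, left, right, kind))
        except (FormatError, CoordinateError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    try:
        return MarkerLibrary(genome, markers)
    except (FormatError, CoordinateError) as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_marker_table(library: MarkerLibrary, path: str | Path) -> None:
    """Write a library in the marker-table TSV dialect (UTF-8, LF)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_MARKER_COLUMNS) + "\n")
        for m in library:
            fh.write(f"{m.allele_id}\t{m.strain_id}\t{m.left_bp}\t{m.right_bp}\t{m.kind}\n")


def load_packaged_library(genome: GenomeMap | None = None) -> MarkerLibrary:
    """The packaged 94-strain intergenic-insertion library (K-12 MG1655).

    Coordinates are transcribed exactly as published for the host strain;
    the default genome length is the U00096.3 chromosome.
    """
    if genome is None:
        genome = GenomeMap("U00096.3", DEFAULT_GENOME_LENGTH, circular=True)
    ref = importlib.resources.files("p1deconv.data").joinpath("i_library.tsv")
    with importlib.resources.as_file(ref) as p:
        return load_marker_table(p, genome)


# ---------------------------------------------------------------------------
# gene annotation

def load_gene_features(path: str | Path) -> list[GeneFeature]:
    """Read gene features from GFF3 (type ``gene``) or a 4-column TSV.

    The TSV dialect is ``gene_id  start  end  strand`` with an optional
    header line.  Coordinates are 1-based inclusive in both dialects.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    first = text.splitlines()[0] if text.splitlines() else ""
    if first.startswith("##gff-version") or _looks_like_gff3(text):
        return _load_gff3_genes(path, text)
    return _load_gene_tsv(path, text)


def _looks_like_gff3(text: str) -> bool:
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        return len(line.split("\t")) == 9
    return False


def _load_gff3_genes(path: Path, text: str) -> list[GeneFeature]:
    genes = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}:{lineno}: GFF3 line has {len(cols)} columns")
        _, _, ftype, start_s, end_s, _, strand, _, attrs = cols
        if ftype != "gene":
            continue
        gene_id = _gff3_id(attrs) or f"gene_{lineno}"
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        try:
            genes.append(GeneFeature(gene_id, start, end, strand))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def _gff3_id(attrs: str) -> str | None:
    for key in ("ID", "Name", "gene_id", "locus_tag"):
        for part in attrs.split(";"):
            k, _, v = part.strip().partition("=")
            if k == key and v:
                return v
    return None


def _load_gene_tsv(path: Path, text: str) -> list[GeneFeature]:
    genes = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns (id start end strand)")
        gene_id, start_s, end_s, strand = parts[:4]
        if lineno == 1 and not (start_s.isdigit() and end_s.isdigit()):
            continue  # header line
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        try:
            genes.append(GeneFeature(gene_id, start, end, strand))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_tsv(genes: Sequence[GeneFeature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tstart_bp\tend_bp\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.start_bp}\t{g.end_bp}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# variants (VCF)

def load_variants(
    path: str | Path,
    genome: GenomeMap,
    contig: str | None = None,
    pass_only: bool = False,
) -> list[CandidateVariant]:
    """Read candidate mutations from a VCF 4.x file (plain or bgzipped).

    One :class:`CandidateVariant` is produced per ALT allele; multi-allelic
    records are split.  All records must sit on a single contig matching the
    genome name (override with ``contig``).  By default the FILTER column is
    ignored; ``pass_only=True`` keeps PASS / unfiltered records only.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"{path}: cannot parse as VCF: {exc}") from None

    expected = contig if contig is not None else genome.name
    variants: list[CandidateVariant] = []
    contigs_seen: set[str] = set()
    for rec in vcf:
        contigs_seen.add(rec.CHROM)
        if rec.CHROM != expected:
            continue
        if pass_only and rec.FILTER is not None:  # cyvcf2: None means PASS/'.'
            continue
        genome.check(rec.POS, f"variant position at {rec.CHROM}:{rec.POS}")
        for alt in rec.ALT:
            var_class = _classify_alleles(rec.REF, alt)
            vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}_{rec.REF}>{alt}"
            variants.append(CandidateVariant(vid, rec.POS, rec.REF, alt, var_class))
    if contigs_seen and expected not in contigs_seen:
        raise FormatError(
            f"{path}: no records on contig {expected!r}; contigs seen: "
            f"{sorted(contigs_seen)}"
        )
    extra = contigs_seen - {expected}
    if extra:
        raise FormatError(
            f"{path}: multi-contig VCF not supported; contigs seen: {sorted(contigs_seen)}"
        )
    return variants


def _classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    return "SNV"  # MNV treated as substitution


def write_variant_vcf(
    variants: Iterable[CandidateVariant], genome: GenomeMap, path: str | Path
) -> None:
    """Write candidate mutations as a minimal valid VCF 4.2 file."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.name},length={genome.length_bp}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.pos_bp):
            fh.write(
                f"{genome.name}\t{v.pos_bp}\t{v.variant_id}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\tPASS\t.\n"
            )
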