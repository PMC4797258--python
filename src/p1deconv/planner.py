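"""Deconvolution experiment planning and plate-reader scoring.

Given the candidate mutations of one screened mutant and a marker library,
the planner chooses the nearest marker for each mutation, predicts its
co-transduction frequency, sizes the number of transductants to pick, and
warns when two mutations share a marker (they may be hard to resolve in one
transduction).  The scoring half turns relative-fluorescence plate readings
into per-well labels and a causative-mutation call: the transduction group
in which wells revert to the wild-type phenotype identifies the causative
mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .genome import CandidateVariant, MarkerLibrary
from .linkage import (
    LinkageModel,
    nearest_markers,
    round_half_up_percent,
    separation_probability,
    wu_frequency,
)

__all__ = [
    "TransductionPlanEntry",
    "WellMeasurement",
    "ReferenceSummary",
    "DeconvolutionCall",
    "build_plan",
    "n_transductants_for_confidence",
    "classify_wells",
    "call_causative",
    "linked_allele_report",
    "load_plate_tsv",
]

DEFAULT_CONFIDENCE = 0.99
DEFAULT_MAX_PICKS = 22  # one picking-robot row block per transduction

WT_REF = "WT_REF"
MUT_REF = "MUT_REF"
CONTROL_GROUPS = (WT_REF, MUT_REF)


@dataclass
class TransductionPlanEntry:
    """One planned transduction: replace one candidate mutation via one marker."""

    variant_id: str
    marker_allele: str
    distance_bp: float
    predicted_freq: float
    n_transductants: int
    uncoverable: bool = False
    capped: bool = False  # the confidence-derived pick count exceeded max_picks
    warnings: list[tuple[str, float, str]] = field(default_factory=list)
    alternate_marker: str | None = None  # near-equidistant runner-up, if any


@dataclass(frozen=True)
class WellMeasurement:
    """One well of the re-screen plate."""

    well_id: str
    group: str  # marker allele / variant group, or WT_REF / MUT_REF
    fluorescence: float
    od600: float

    def __post_init__(self) -> None:
        if self.od600 <= 0:
            raise ValueError(f"well {self.well_id}: OD600 must be positive, got {self.od600}")
        if self.fluorescence < 0:
            raise ValueError(f"well {self.well_id}: negative fluorescence")

    @property
    def relative_fluorescence(self) -> float:
        return self.fluorescence / self.od600


@dataclass(frozen=True)
class ReferenceSummary:
    """Log-scale relative-fluorescence reference (mean and SD) for one control."""

    log_mean: float
    log_sd: float

    @staticmethod
    def from_wells(wells: Sequence[WellMeasurement]) -> "ReferenceSummary":
        logs = [math.log(w.relative_fluorescence) for w in wells]
        n = len(logs)
        if n == 0:
            raise ValueError("no reference wells")
        mean = sum(logs) / n
        var = sum((x - mean) ** 2 for x in logs) / (n - 1) if n > 1 else 0.0
        return ReferenceSummary(mean, math.sqrt(var))


@dataclass
class DeconvolutionCall:
    """Causative-mutation call for one screened mutant."""

    mutant_id: str
    causative_variant_id: str | None
    call: str  # full | partial | none | ambiguous
    reverted_counts: dict[str, int]
    intermediate_counts: dict[str, int] = field(default_factory=dict)
    qualifying_groups: list[str] = field(default_factory=list)


def n_transductants_for_confidence(freq: float, confidence: float) -> int:
    """Smallest n with ``1 - (1-f)^n >= confidence``.

    This is the number of transductants to pick so that, with probability at
    least ``confidence``, at least one has the mutation replaced.
    """
    if not (0 < freq <= 1):
        raise ValueError(
            f"frequency must be in (0, 1], got {freq}"
            + (" (zero linkage: no finite pick count suffices)" if freq == 0 else "")
        )
    if not (0 < confidence < 1):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if freq == 1.0:
        return 1
    n = math.ceil(math.log(1.0 - confidence) / math.log(1.0 - freq))
    # guard against float edge cases at the boundary
    while 1.0 - (1.0 - freq) ** n < confidence:
        n += 1
    while n > 1 and 1.0 - (1.0 - freq) ** (n - 1) >= confidence:
        n -= 1
    return max(1, n)


def build_plan(
    variants: Sequence[CandidateVariant],
    library: MarkerLibrary,
    model: LinkageModel | None = None,
    confidence: float = DEFAULT_CONFIDENCE,
    max_picks: int = DEFAULT_MAX_PICKS,
    equidistant_tolerance_bp: float = 1_000.0,
) -> list[TransductionPlanEntry]:
    """Plan one transduction per candidate mutation.

    Each variant gets its nearest marker, the predicted co-transduction
    frequency, and ``min(max_picks, n_for_confidence)`` transductants.  An
    entry whose frequency is 0 (variant beyond the fragment length from every
    marker) is still emitted, flagged uncoverable, with ``max_picks`` picks.
    Variant pairs sharing a marker are cross-annotated with their separation
    probability; the annotation is symmetric.
    """
    if not variants:
        raise ValueError("no variants to plan")
    if model is None:
        model = LinkageModel()
    entries: list[TransductionPlanEntry] = []
    for v in variants:
        ranked = nearest_markers(v.pos_bp, library, k=min(2, len(library)))
        marker, d = ranked[0]
        f = wu_frequency(d, model)
        alternate = None
        if len(ranked) > 1 and ranked[1][1] - d <= equidistant_tolerance_bp:
            alternate = ranked[0 + 1][0].allele_id
        if f == 0.0:
            entries.append(
                TransductionPlanEntry(v.variant_id, marker.allele_id, d, f,
                                      max_picks, uncoverable=True,
                                      alternate_marker=alternate)
            )
            continue
        n_uncapped = n_transductants_for_confidence(f, confidence)
        capped = n_uncapped > max_picks
        entries.append(
            TransductionPlanEntry(v.variant_id, marker.allele_id, d, f,
                                  min(max_picks, n_uncapped), capped=capped,
                                  alternate_marker=alternate)
        )
    # symmetric same-marker warnings
    for i, a in enumerate(entries):
        for b in entries[i + 1:]:
            if a.marker_allele != b.marker_allele:
                continue
            near, far = sorted((a, b), key=lambda e: e.distance_bp)
            sep = separation_probability(near.distance_bp, far.distance_bp, model)
            note = (
                f"shares marker {a.marker_allele}; separation probability "
                f"{round_half_up_percent(sep)}%"
            )
            a.warnings.append((b.variant_id, sep, note))
            b.warnings.append((a.variant_id, sep, note))
    return entries


def classify_wells(
    wells: Sequence[WellMeasurement],
    wt_reference: ReferenceSummary,
    mutant_reference: ReferenceSummary,
    margin_g: float = 1.0,
) -> dict[str, str]:
    """Label each well reverted / mutant-like / intermediate.

    Classification is on log relative fluorescence (the phenotype is a
    ratio, so multiplicative): a well at least ``margin_g`` pooled SDs
    closer to the wild-type mean than to the mutant mean is ``reverted``;
    the mirror case is ``mutant-like``; anything in between is
    ``intermediate``.  With zero-dispersion references the margin degrades
    to a nearest-mean rule.
    """
    pooled_sd = math.sqrt((wt_reference.log_sd ** 2 + mutant_reference.log_sd ** 2) / 2)
    if pooled_sd == 0.0:
        import warnings

        warnings.warn(
            "zero-dispersion references: margin test reduces to nearest-mean",
            stacklevel=2,
        )
    margin = margin_g * pooled_sd
    labels: dict[str, str] = {}
    for w in wells:
        x = math.log(w.relative_fluorescence)
        d_wt = abs(x - wt_reference.log_mean)
        d_mut = abs(x - mutant_reference.log_mean)
        if d_mut - d_wt >= margin and d_mut > d_wt:
            labels[w.well_id] = "reverted"
        elif d_wt - d_mut >= margin and d_wt > d_mut:
            labels[w.well_id] = "mutant-like"
        else:
            labels[w.well_id] = "intermediate"
    return labels


def _tally(
    wells: Sequence[WellMeasurement], labels: Mapping[str, str]
) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    reverted: dict[str, int] = {}
    intermediate: dict[str, int] = {}
    mutant_like: dict[str, int] = {}
    for w in wells:
        if w.group in CONTROL_GROUPS:
            continue
        for d in (reverted, intermediate, mutant_like):
            d.setdefault(w.group, 0)
        lab = labels[w.well_id]
        if lab == "reverted":
            reverted[w.group] += 1
        elif lab == "intermediate":
            intermediate[w.group] += 1
        else:
            mutant_like[w.group] += 1
    return reverted, intermediate, mutant_like


def call_causative(
    wells: Sequence[WellMeasurement],
    labels: Mapping[str, str],
    plan: Sequence[TransductionPlanEntry],
    mutant_id: str = "mutant",
    revertant_threshold: int = 2,
) -> DeconvolutionCall:
    """Call the causative mutation from per-well labels.

    A transduction group qualifies when at least ``revertant_threshold``
    wells reverted.  Exactly one qualifying group -> ``full`` call naming
    that group's planned variant; several -> ``ambiguous``; none, but some
    group shows that many intermediate wells -> ``partial`` (replacement
    only partially restored the wild-type phenotype); otherwise ``none``.
    """
    by_group: dict[str, TransductionPlanEntry] = {}
    for e in plan:
        # a group on the plate is keyed by the variant it tests; marker ids
        # are accepted too when unambiguous
        by_group[e.variant_id] = e
        by_group.setdefault(e.marker_allele, e)
    reverted, intermediate, _ = _tally(wells, labels)
    for group in reverted:
        if group not in by_group:
            raise ValueError(f"plate group {group!r} does not appear in the plan")
    qualifying = sorted(g for g, c in reverted.items() if c >= revertant_threshold)
    if len(qualifying) == 1:
        g = qualifying[0]
        return DeconvolutionCall(mutant_id, by_group[g].variant_id, "full",
                                 reverted, intermediate, qualifying)
    if len(qualifying) > 1:
        return DeconvolutionCall(mutant_id, None, "ambiguous",
                                 reverted, intermediate, qualifying)
    partial = sorted(
        g for g, c in intermediate.items() if c >= revertant_threshold
    )
    if partial:
        return DeconvolutionCall(mutant_id, by_group[partial[0]].variant_id,
                                 "partial", reverted, intermediate, partial)
    return DeconvolutionCall(mutant_id, None, "none", reverted, intermediate, [])


def linked_allele_report(
    wells: Sequence[WellMeasurement],
    labels: Mapping[str, str],
    call: DeconvolutionCall,
    plan: Sequence[TransductionPlanEntry],
) -> dict:
    """Candidate marker-tagged mutant alleles from the causative group.

    Transductants of the causative group that did NOT revert carry the
    selectable cassette linked to the still-present causative mutation;
    they are the material for moving the mutation into a clean background.
    The expected fraction of such wells is ``1 - predicted_freq``.
    """
    if call.causative_variant_id is None:
        return {"causative_group": None, "tagged_wells": [], "expected_fraction": None,
                "advisory": "no causative call; nothing to tag"}
    entry = next(e for e in plan if e.variant_id == call.causative_variant_id)
    group_wells = [
        w for w in wells
        if w.group not in CONTROL_GROUPS
        and (w.group == entry.variant_id or w.group == entry.marker_allele)
    ]
    tagged = [w.well_id for w in group_wells if labels[w.well_id] == "mutant-like"]
    advisory = None
    if not tagged:
        advisory = (
            "every transductant reverted; re-transduce and screen more picks to "
            "recover a marker-linked mutant allele"
        )
    return {
        "causative_group": entry.variant_id,
        "marker_allele": entry.marker_allele,
        "tagged_wells": tagged,
        "expected_fraction": 1.0 - entry.predicted_freq,
        "advisory": advisory,
    }


# ---------------------------------------------------------------------------
# I/O

def load_plate_tsv(path: str | Path) -> list[WellMeasurement]:
    """Read plate measurements: ``well_id  group  fluorescence  od600``."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty plate file")
    wells = []
    start = 1 if lines[0].startswith("well_id") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        well_id, group, fluo_s, od_s = parts
        wells.append(WellMeasurement(well_id, group, float(fluo_s), float(od_s)))
    return wells


def write_plan_tsv(plan: Sequence[TransductionPlanEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "variant_id\tmarker_allele\tdistance_bp\tpredicted_freq\tfreq_percent\t"
            "n_picks\twarnings\n"
        )
        for e in plan:
            notes = []
            if e.uncoverable:
                notes.append("UNCOVERABLE:no marker within fragment length")
            if e.capped:
                notes.append("CAPPED:confidence requires more picks than max")
            for other, sep, _ in e.warnings:
                notes.append(f"SHARED_MARKER:{other}:sep={sep:.3f}")
            fh.write(
                f"{e.variant_id}\t{e.marker_allele}\t{round(e.distance_bp)}\t"
                f"{e.predicted_freq:.6f}\t{round_half_up_percent(e.predicted_freq)}\t"
                f"{e.n_transductants}\t{';'.join(notes) if notes else '.'}\n"
            )


def write_calls_tsv(call: DeconvolutionCall, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mutant_id\tcall\tcausative_variant\tgroup\treverted\tintermediate\n")
        groups = sorted(set(call.reverted_counts) | set(call.intermediate_counts))
        for g in groups:
            fh.write(
                f"{call.mutant_id}\t{call.call}\t{call.causative_variant_id or '.'}\t"
                f"{g}\t{call.reverted_counts.get(g, 0)}\t"
                f"{call.intermediate_counts.get(g, 0)}\n"
            )
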