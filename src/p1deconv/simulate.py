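"""Mutagenesis dose model, stochastic transduction, and full-screen Monte Carlo.

The forward-genomic workflow being modelled: mutagenize a population so each
cell carries a Poisson number of point mutations, screen for a phenotype,
sequence the hits (with imperfect detection), then for every sequenced
mutation transduce in the nearest selectable marker so that co-transferred
wild-type sequence replaces nearby loci, and re-screen transductants for
phenotype reversion.  The mutation whose replacement reverts the phenotype
is causative.

The replaced fragment is modelled by independent per-side extents with
survival function ``P(X >= d) = (1 - d/L)^3``, which makes the marginal
co-replacement probability of a locus at distance ``d`` exactly the Wu
frequency, and makes same-side replacement nested (a far locus is never
replaced without every nearer one).

This module also hosts the synthetic fixture generator used by the test
suite and the examples: a circular annotation, a designed marker library,
a mutant VCF and one simulated re-screen plate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import (
    CandidateVariant,
    GeneFeature,
    GenomeMap,
    MarkerInsertion,
    MarkerLibrary,
    signed_circular_offset,
    write_gene_tsv,
    write_marker_table,
    write_variant_vcf,
)
from .linkage import LinkageModel
from .planner import (
    MUT_REF,
    WT_REF,
    ReferenceSummary,
    WellMeasurement,
    build_plan,
    call_causative,
    classify_wells,
)

__all__ = [
    "DoseModel",
    "FragmentModel",
    "ScreenSimConfig",
    "MutantGenome",
    "TransductantOutcome",
    "SimulationSummary",
    "mutation_count_probabilities",
    "dose_for_target",
    "simulate_mutant_genomes",
    "simulate_detection",
    "sample_replacement_extent",
    "simulate_transduction",
    "run_deconvolution_sim",
    "synthetic_annotation",
    "generate_fixtures",
    "load_sim_config",
]


# ---------------------------------------------------------------------------
# dose model

@dataclass(frozen=True)
class DoseModel:
    """Poisson mutagenesis dose: mean mutations per genome ``lam``."""

    lam: float = 6.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"dose lambda must be non-negative, got {self.lam}")


def mutation_count_probabilities(dose: DoseModel) -> tuple[float, float, float]:
    """(P0, P1, P>1) for the Poisson mutation-count distribution.

    P0 is the fraction of clones the mutagenesis misses entirely, P1 the
    single-mutation clones (ideal for screening), P>1 the multi-mutation
    clones whose hits need deconvolution.
    """
    from scipy.stats import poisson

    p0 = float(poisson.pmf(0, dose.lam))
    p1 = float(poisson.pmf(1, dose.lam))
    return p0, p1, 1.0 - p0 - p1


def dose_for_target(min_mutated_fraction: float) -> float:
    """Dose lambda such that at least this fraction of clones carry >=1 mutation."""
    if not (0 < min_mutated_fraction < 1):
        raise ValueError(
            f"target mutated fraction must be in (0, 1), got {min_mutated_fraction}"
        )
    return -math.log(1.0 - min_mutated_fraction)


# ---------------------------------------------------------------------------
# fragment model

@dataclass(frozen=True)
class FragmentModel:
    """Stochastic replaced-fragment model around a selected marker.

    Each side's replacement extent is drawn as ``X = L * (1 - U^(1/3))`` with
    U uniform, i.e. ``P(X >= d) = (1 - d/L)^3``; left and right extents are
    independent.
    """

    fragment_length_L: int = 100_000

    def linkage(self) -> LinkageModel:
        return LinkageModel(self.fragment_length_L)


def sample_replacement_extent(
    model: FragmentModel, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw (left, right) replacement extents; shape (2,) or (size, 2)."""
    shape = (2,) if size is None else (size, 2)
    u = rng.random(shape)
    return model.fragment_length_L * (1.0 - np.cbrt(u))


@dataclass
class MutantGenome:
    """One mutagenized clone: mutation positions and which are causative."""

    positions: list[int]
    causative: list[bool]
    screened: bool

    @property
    def causative_positions(self) -> list[int]:
        return [p for p, c in zip(self.positions, self.causative) if c]


def simulate_mutant_genomes(
    genome: GenomeMap,
    n_mutants: int,
    lam: float,
    causative_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[MutantGenome], float]:
    """Mutagenize ``n_mutants`` clones and screen them.

    Each clone receives Poisson(``lam``) mutations at i.i.d. uniform
    positions; each mutation is phenotype-conferring independently with
    probability ``causative_fraction``.  A clone passes the screen iff it
    carries at least one causative mutation.  Returns the clones and the
    screen retention fraction.
    """
    if not (0 <= causative_fraction <= 1):
        raise ValueError(f"causative_fraction must be in [0, 1], got {causative_fraction}")
    counts = rng.poisson(lam, size=n_mutants)
    genomes = []
    n_pass = 0
    for c in counts:
        pos = rng.integers(1, genome.length_bp + 1, size=c)
        caus = rng.random(c) < causative_fraction
        screened = bool(caus.any())
        n_pass += screened
        genomes.append(MutantGenome(pos.tolist(), caus.tolist(), screened))
    return genomes, (n_pass / n_mutants if n_mutants else 0.0)


def simulate_detection(
    positions: Sequence[int], sensitivity: float, rng: np.random.Generator
) -> list[int]:
    """WGS variant calling with a flat per-mutation sensitivity."""
    if not (0 <= sensitivity <= 1):
        raise ValueError(f"sensitivity must be in [0, 1], got {sensitivity}")
    if not len(positions):
        return []
    keep = rng.random(len(positions)) < sensitivity
    return [p for p, k in zip(positions, keep) if k]


@dataclass(frozen=True)
class TransductantOutcome:
    """One picked transductant: which recipient mutations got replaced."""

    replaced: tuple[bool, ...]
    reverted: bool


def simulate_transduction(
    mutation_positions: Sequence[int],
    causative: Sequence[bool],
    marker: MarkerInsertion,
    model: FragmentModel,
    n_picks: int,
    genome: GenomeMap,
    rng: np.random.Generator,
) -> list[TransductantOutcome]:
    """Simulate picking ``n_picks`` transductants of one marker.

    Per pick, independent left/right replacement extents are drawn around the
    marker's reference point; a recipient mutation is replaced iff its signed
    circular offset falls within the replaced arc.  The phenotype reverts iff
    every causative mutation is replaced.
    """
    offsets = np.array(
        [signed_circular_offset(p, marker.midpoint, genome) for p in mutation_positions]
    )
    caus = np.asarray(causative, dtype=bool)
    extents = sample_replacement_extent(model, rng, size=n_picks)  # (n_picks, 2)
    outcomes = []
    for i in range(n_picks):
        left, right = extents[i]
        if offsets.size:
            replaced = np.where(offsets >= 0, offsets <= right, -offsets <= left)
        else:
            replaced = np.zeros(0, dtype=bool)
        reverted = bool(replaced[caus].all()) if caus.any() else False
        outcomes.append(TransductantOutcome(tuple(bool(r) for r in replaced), reverted))
    return outcomes


# ---------------------------------------------------------------------------
# full-screen Monte Carlo

@dataclass
class ScreenSimConfig:
    """Study conditions for the end-to-end screen simulation.

    Defaults mirror the validated bench protocol: ~6 mutations per genome,
    22 transductants picked per transduction, and a requirement of at least
    2 reverted wells to call a group causative.
    """

    genome: GenomeMap = field(default_factory=GenomeMap)
    n_reps: int = 1000
    lam: float = 6.0
    causative_fraction: float = 0.05
    detection_sensitivity: float = 1.0
    n_picks: int = 22
    revertant_threshold: int = 2
    plate_noise_sd: float = 0.1  # SD of log relative fluorescence within a class
    wt_rel_fluorescence: float = 100.0
    mutant_rel_fluorescence: float = 1000.0
    n_control_wells: int = 8
    fragment_length_L: int = 100_000
    fixed_mutation_count: int | None = None  # validation mode: exactly this many mutations
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("causative_fraction", "detection_sensitivity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible simulation")
        if self.n_picks < 1:
            raise ValueError(f"n_picks must be >= 1, got {self.n_picks}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")


@dataclass
class SimulationSummary:
    """Monte-Carlo outcome tallies over ``n_reps`` simulated screened mutants."""

    n_reps: int
    n_success: int
    success_rate: float
    wilson_ci: tuple[float, float]
    failure_modes: dict[str, int]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"n_reps\t{self.n_reps}\n")
            fh.write(f"n_success\t{self.n_success}\n")
            fh.write(f"success_rate\t{self.success_rate:.6f}\n")
            fh.write(f"wilson_ci_low\t{self.wilson_ci[0]:.6f}\n")
            fh.write(f"wilson_ci_high\t{self.wilson_ci[1]:.6f}\n")
            for mode in sorted(self.failure_modes):
                fh.write(f"failures.{mode}\t{self.failure_modes[mode]}\n")


def _wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return (float(lo), float(hi))


FAILURE_MODES = (
    "causative_undetected_by_WGS",
    "no_revertant_among_picks",
    "ambiguous_call",
    "none_call",
)


def _sample_screened_mutant(
    config: ScreenSimConfig, rng: np.random.Generator
) -> MutantGenome:
    """Rejection-sample one clone that passes the phenotype screen."""
    G = config.genome.length_bp
    while True:
        c = (config.fixed_mutation_count if config.fixed_mutation_count is not None
             else rng.poisson(config.lam))
        if c == 0:
            continue
        caus = rng.random(c) < config.causative_fraction
        if not caus.any():
            continue
        pos = rng.integers(1, G + 1, size=c)
        return MutantGenome(pos.tolist(), caus.tolist(), True)


def run_deconvolution_sim(
    config: ScreenSimConfig,
    library: MarkerLibrary,
    verbose_log: list | None = None,
) -> SimulationSummary:
    """Monte Carlo of the full screen-and-deconvolve workflow.

    Per replicate: draw a screened mutant, call its mutations by WGS with the
    configured sensitivity, plan one transduction per detected mutation
    (nearest marker), simulate the picked transductants with the stochastic
    fragment model, synthesize plate readings (log-normal noise around the
    wild-type mean for reverted wells and the mutant mean otherwise), then
    classify wells and call the causative group.  Success means a ``full``
    call naming a truly causative mutation.
    """
    if len(library) == 0:
        raise ValueError("empty marker library")
    if config.causative_fraction == 0:
        raise ValueError("causative_fraction must be positive: no clone can pass the screen")
    rng = np.random.default_rng(config.seed)
    frag = FragmentModel(config.fragment_length_L)
    model = frag.linkage()
    log_wt = math.log(config.wt_rel_fluorescence)
    log_mut = math.log(config.mutant_rel_fluorescence)
    wt_ref = ReferenceSummary(log_wt, config.plate_noise_sd)
    mut_ref = ReferenceSummary(log_mut, config.plate_noise_sd)

    n_success = 0
    failures = {m: 0 for m in FAILURE_MODES}
    for rep in range(config.n_reps):
        mut = _sample_screened_mutant(config, rng)
        detected_idx = [
            i for i in range(len(mut.positions))
            if rng.random() < config.detection_sensitivity
        ]
        detected_causative = [i for i in detected_idx if mut.causative[i]]
        if not detected_causative:
            failures["causative_undetected_by_WGS"] += 1
            if verbose_log is not None:
                verbose_log.append((rep, "causative_undetected_by_WGS", None))
            continue
        variants = [
            CandidateVariant(f"v{i}", int(mut.positions[i]), "N", "A", "SNV")
            for i in detected_idx
        ]
        plan = build_plan(variants, library, model, max_picks=config.n_picks)
        wells: list[WellMeasurement] = []
        any_revertant = False
        for entry in plan:
            marker = library[entry.marker_allele]
            outcomes = simulate_transduction(
                mut.positions, mut.causative, marker, frag,
                config.n_picks, config.genome, rng,
            )
            for j, out in enumerate(outcomes):
                any_revertant = any_revertant or out.reverted
                mean = log_wt if out.reverted else log_mut
                x = mean + config.plate_noise_sd * rng.standard_normal() \
                    if config.plate_noise_sd > 0 else mean
                wells.append(
                    WellMeasurement(f"{entry.variant_id}_w{j}", entry.variant_id,
                                    math.exp(x), 1.0)
                )
        labels = classify_wells(wells, wt_ref, mut_ref)
        call = call_causative(
            wells, labels, plan,
            revertant_threshold=config.revertant_threshold,
        )
        truly_causative = {
            f"v{i}" for i in detected_idx if mut.causative[i]
        }
        if call.call == "full" and call.causative_variant_id in truly_causative:
            n_success += 1
            if verbose_log is not None:
                verbose_log.append((rep, "success", call.causative_variant_id))
            continue
        if call.call == "ambiguous":
            mode = "ambiguous_call"
        elif call.call == "full":
            mode = "wrong_variant_call"
        elif call.call == "partial":
            mode = "partial_call"
        elif not any_revertant:
            mode = "no_revertant_among_picks"
        else:
            mode = "none_call"
        failures[mode] = failures.get(mode, 0) + 1
        if verbose_log is not None:
            verbose_log.append((rep, mode, call.causative_variant_id))

    rate = n_success / config.n_reps
    return SimulationSummary(
        n_reps=config.n_reps,
        n_success=n_success,
        success_rate=rate,
        wilson_ci=_wilson_interval(n_success, config.n_reps),
        failure_modes=failures,
    )


# ---------------------------------------------------------------------------
# synthetic fixtures

def synthetic_annotation(
    genome: GenomeMap,
    rng: np.random.Generator,
    mean_gene_bp: float = 1_000.0,
    mean_gap_bp: float = 300.0,
) -> list[GeneFeature]:
    """A circular bacterial-style annotation: alternating genes and gaps.

    Gene lengths and intergenic gaps are exponential with the given means
    (bacterial genomes are gene-dense; the defaults give ~77% coding),
    strands are fair-coin.  Walks the circle once; the final partial gene is
    dropped so features never wrap the origin.
    """
    genes = []
    pos = 1 + int(rng.integers(0, max(1, int(mean_gap_bp))))
    i = 0
    while True:
        glen = max(60, int(rng.exponential(mean_gene_bp)))
        end = pos + glen - 1
        if end >= genome.length_bp:
            break
        i += 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneFeature(f"g{i:04d}", pos, end, strand))
        gap = max(2, int(rng.exponential(mean_gap_bp)))
        pos = end + 1 + gap
        if pos >= genome.length_bp:
            break
    return genes


def generate_fixtures(
    out_dir: str | Path,
    seed: int,
    genome_length: int = 500_000,
    mean_gene_bp: float = 1_000.0,
    mean_gap_bp: float = 300.0,
    target_spacing_bp: int = 50_000,
    lam: float = 6.0,
    n_variants: int | None = None,
    plate_noise_sd: float = 0.1,
) -> dict[str, Path]:
    """Write a self-consistent synthetic fixture set.

    Produces, in ``out_dir``: ``genes.tsv`` (annotation), ``markers.tsv``
    (a library designed on that annotation at the target spacing),
    ``mutant.vcf`` (one mutagenized clone, Poisson(``lam``) SNVs unless
    ``n_variants`` forces the count) and ``plate.tsv`` (one simulated
    re-screen of that clone).  Byte-identical for identical arguments.
    """
    from .design import DesignSpec, classify_intergenic_regions, place_markers

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome = GenomeMap("synthetic", genome_length, circular=True)

    genes = synthetic_annotation(genome, rng, mean_gene_bp, mean_gap_bp)
    genes_path = out_dir / "genes.tsv"
    write_gene_tsv(genes, genes_path)

    regions = classify_intergenic_regions(genes, genome)
    spec = DesignSpec(target_spacing_bp=target_spacing_bp)
    library, _ = place_markers(regions, spec, genome)
    markers_path = out_dir / "markers.tsv"
    write_marker_table(library, markers_path)

    n_mut = int(rng.poisson(lam)) if n_variants is None else n_variants
    n_mut = max(1, n_mut)
    positions = sorted(int(p) for p in rng.integers(1, genome_length + 1, size=n_mut))
    bases = "ACGT"
    variants = []
    for i, p in enumerate(positions, start=1):
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        variants.append(CandidateVariant(f"mut{i}", p, ref, alt, "SNV"))
    vcf_path = out_dir / "mutant.vcf"
    write_variant_vcf(variants, genome, vcf_path)

    # one simulated re-screen plate: the first variant is causative
    frag = FragmentModel()
    plate_path = out_dir / "plate.tsv"
    causative = [i == 0 for i in range(len(variants))]
    plan = build_plan(variants, library, frag.linkage())
    log_wt, log_mut = math.log(100.0), math.log(1000.0)
    with open(plate_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("well_id\tgroup\tfluorescence\tod600\n")
        for k in range(8):
            x = log_wt + plate_noise_sd * rng.standard_normal()
            fh.write(f"{WT_REF}_w{k}\t{WT_REF}\t{math.exp(x):.4f}\t1.0\n")
            x = log_mut + plate_noise_sd * rng.standard_normal()
            fh.write(f"{MUT_REF}_w{k}\t{MUT_REF}\t{math.exp(x):.4f}\t1.0\n")
        for entry in plan:
            marker = library[entry.marker_allele]
            outcomes = simulate_transduction(
                [v.pos_bp for v in variants], causative, marker, frag,
                22, genome, rng,
            )
            for j, out in enumerate(outcomes):
                mean = log_wt if out.reverted else log_mut
                x = mean + plate_noise_sd * rng.standard_normal()
                fh.write(
                    f"{entry.variant_id}_w{j}\t{entry.variant_id}\t"
                    f"{math.exp(x):.4f}\t1.0\n"
                )
    return {
        "genes": genes_path,
        "markers": markers_path,
        "vcf": vcf_path,
        "plate": plate_path,
    }


# ---------------------------------------------------------------------------
# config file

_CONFIG_KEYS = {
    "genome_length": int,
    "genome_name": str,
    "n_reps": int,
    "lam": float,
    "causative_fraction": float,
    "detection_sensitivity": float,
    "n_picks": int,
    "revertant_threshold": int,
    "plate_noise_sd": float,
    "wt_rel_fluorescence": float,
    "mutant_rel_fluorescence": float,
    "fragment_length_L": int,
    "seed": int,
}


def load_sim_config(path: str | Path, **overrides) -> ScreenSimConfig:
    """Read a flat key-value (``key: value``) simulation config file.

    Unknown keys are rejected; keyword overrides win over file values.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected flat key-value pairs")
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    genome = GenomeMap(
        str(merged.pop("genome_name", "chromosome")),
        int(merged.pop("genome_length", GenomeMap().length_bp)),
    )
    kwargs = {}
    for key, value in merged.items():
        caster = _CONFIG_KEYS.get(key, lambda v: v)
        kwargs[key] = caster(value)
    return ScreenSimConfig(genome=genome, **kwargs)
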