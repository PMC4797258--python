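# Methods

## Linkage model

Co-transduction of a locus with a selected marker is modelled by Wu's
formula, *f*(*d*) = (1 − *d*/*L*)³ for 0 ≤ *d* < *L* and 0 beyond, where
*d* is the distance from the locus to the marker's reference point and *L*
is the transducing-segment length (default 100,000 bp for phage P1).  The
cubic form is the classical head-full packaging argument: a transduced
fragment of length *L* covers both the marker and a locus *d* away only if
the fragment's left end falls in a window whose size shrinks linearly with
*d*, and selection plus recombination geometry contribute two further
linear factors.  The package treats the exponent as fixed; the curve's
integer-rounded predictions at the benchmark distance pairs
(20/30 kb → 17%, 10/20 kb → 22%, 15/20 kb → 10%, and ≤3% for loci 1 kb
apart) discriminate it sharply from, e.g., a quadratic, and the test suite
pins those values.

Distance conventions.  All coordinates are 1-based inclusive on a single
circular chromosome; distances are shortest-arc.  An intergenic cassette
inserted between bases *l* and *r* is referenced by the midpoint
(*l* + *r*)/2, which may be half-integral; a gene deletion-replacement is
referenced by whichever interval edge is nearer the query locus, because
the replaced gene's full span carries the cassette.  Internally distances
stay real-valued; output tables round to whole bp, and probabilities
printed as percentages round half-up to integers.  The genome length
defaults to 4,641,652 bp (the *E. coli* K-12 MG1655 chromosome) and is
overridable everywhere — nothing hard-wires one organism.

Separation of close mutations.  For two mutations on the same side of a
marker at distances *d*₁ ≤ *d*₂, replacement is nested (the donor fragment
is contiguous), so one transduction separates them — replaces the near one
while keeping the far one — with probability *f*(*d*₁) − *f*(*d*₂).  Pairs
on opposite sides of a marker are handled in the simulator under
independence of the two sides and are flagged as an extrapolation in
planner reports; only same-interval pairs have a quantified model.

## Coverage

The worst-covered point of a marker library on a circular genome is the
midpoint of the widest gap between adjacent reference points, so
`coverage_summary` scans gap midpoints analytically rather than sampling
positions; a brute-force position scan on small genomes is kept as an
oracle test.  The packaged 94-insertion library has mean circular spacing
49.4 kb and a widest gap of 62,574 bp (i-4 to i-5), giving a worst-case
frequency of 0.324 under the midpoint convention.  The library validator's
default floor is 0.35 — the nominal coverage claim for ~50 kb spacing —
and the packaged library's worst gap sits just below it; the audit reports
this honestly rather than special-casing it.  Whether the historical
figure of ~35% was computed with a different distance convention or
jointly over two libraries is unknowable from the published coordinates
alone, so the acceptance check asserts a 0.30–0.40 band, not an equality.

## Library design

`place_markers` is greedy grid-and-snap: ideal sites on a regular grid at
the target spacing, each snapped to the nearest point inside any
intergenic region (smallest shift; ties to the lower coordinate), then a
coverage audit of the snapped layout.  A dynamic program minimizing the
maximum gap would be globally optimal but the observed spacings of real
libraries (44–63 kb around a 50 kb target) are exactly what grid-and-snap
produces, and it is deterministic and explainable site by site.
Overlapping genes are merged into opaque blocks before region extraction;
region orientation comes from the outermost strands of the flanking blocks
((+,−) convergent, (−,+) divergent, equal strands codirectional).
Insertions are single-point (left = snapped position, right = left + 1),
with no buffer from gene boundaries by default.

## Planning and scoring

Pick counts.  The number of transductants to pick for a variant with
predicted frequency *f* is the smallest *n* with 1 − (1 − *f*)ⁿ ≥ *c*,
default confidence *c* = 0.99, capped at 22 (the single-plate robot pick
of the bench protocol; at the 0.35 coverage floor the uncapped requirement
is 11, so 22 is comfortable).  Variants with *f* = 0 are planned at the cap
and flagged uncoverable, never dropped.

Well classification is on log relative fluorescence (fluorescence/OD600
ratios are multiplicative): a well at least *g* pooled-SDs closer to the
wild-type reference mean than to the mutant reference mean is `reverted`,
the mirror case `mutant-like`, otherwise `intermediate`; *g* defaults to 1
and zero-dispersion references degrade to nearest-mean with a warning.
A transduction group with at least *m* reverted wells (default *m* = 2,
configurable to 1; two wells guard against single-well outliers) qualifies
as causative; exactly one qualifying group gives a `full` call, several
give `ambiguous`, and a group with ≥ *m* intermediate wells but no
qualifying group gives `partial` — the signature of a replacement that
only partially restores the wild-type phenotype.  Plate groups are keyed
by variant rather than by marker so two variants sharing a marker remain
distinct transductions; the scorer accepts marker-keyed groups when
unambiguous.

Non-reverted transductants of the causative group are reported as
candidate marker-tagged mutant alleles (expected fraction 1 − *f*), useful
for moving the mutation into a clean background.

## Simulation

Dose.  Mutation counts per clone are Poisson(λ); the class probabilities
P0 = e^(−λ), P1 = λe^(−λ), P>1 = 1 − P0 − P1 quantify the screen's
trade-off, and λ = −ln(1 − q) inverts the requirement that a fraction *q*
of clones be mutated.  The default λ = 6 reflects a dose at which almost
no clone escapes mutagenesis (P0 ≈ 0.25%).

Fragment model.  Each side of the marker gets an independent replacement
extent X = L(1 − U^{1/3}), U uniform — the inverse-CDF of the survival
function (1 − d/L)³ — so the marginal co-replacement probability of any
locus equals the linkage curve exactly and same-side replacement is nested
by construction.  This reproduces both the single-locus and the pair
statistics without committing to a mechanistic crossover model; an
explicit fragment-plus-double-crossover sampler would be the natural
extension if crossover-position data ever mattered.

End-to-end Monte Carlo.  Per replicate: rejection-sample a clone that
passes the screen (≥1 causative mutation; causativeness is i.i.d.
Bernoulli per mutation with probability `causative_fraction`), detect each
mutation with the configured WGS sensitivity, plan one transduction per
detected mutation, sample the picked transductants, synthesize plate
readings (log-normal noise of configurable SD around the wild-type mean
for reverted wells, the mutant mean otherwise), classify, and call.
Success = a `full` call naming a truly causative mutation.  Failures are
tallied by mode (causative undetected by WGS, no revertant among picks,
ambiguous call, none call, plus rarer wrong-variant and partial-call
outcomes), and the success rate carries a 95% Wilson interval
(statsmodels).  A single seeded NumPy generator drives every draw in
documented call order, so summaries are byte-reproducible.

`fixed_mutation_count` replaces the Poisson draw with an exact count; it
exists for validation scenarios that isolate one stage — e.g. a
single-causative-mutation screen measures pure pick-level power, where the
success rate must approach 1 − (1 − f)ⁿ and exceeds 99.9% whenever every
locus is within 25 kb of a marker and 22 picks are taken.  With a full
Poisson mutation load on a deliberately small genome, ambiguous calls
dominate instead — the ~100 kb fragment spans a large fraction of a toy
chromosome, so neighbouring mutations co-revert; this is a property of the
scaled-down geometry, not of the method on a real-size genome.

Problem sizes.  The shipped validation scenarios use 10⁵ draws for
sampler-vs-curve checks at 19 distances (3·SE tolerance), 10⁴ replicates
for the end-to-end screen, and a 500 kb toy genome with ten markers at
50 kb spacing; these sizes give Monte-Carlo error well below every margin
asserted.

## Synthetic data generator

`synthetic_annotation` emulates a gene-dense circular bacterial genome:
exponential gene lengths (mean 1 kb, floor 60 bp), exponential intergenic
gaps (mean 300 bp, ~77% coding), strands i.i.d. fair-coin.  It reproduces
the features the design and planning code depends on — gene density,
intergenic-gap statistics, orientation-class frequencies (¼ convergent,
½ codirectional, ¼ divergent under fair-coin strands) — and deliberately
omits operon structure, strand-biased gene clustering, GC skew,
replication-origin asymmetry and mutational hotspots.  Passing tests on
these fixtures therefore validate the geometry and logic of the
algorithms, not organism-specific annotation quirks; the packaged real
library is the bridge to real coordinates.  `generate_fixtures` writes a
self-consistent annotation + designed library + mutant VCF + simulated
plate, byte-identical per seed.

## Degenerate inputs and tie-breaks

Empty marker tables, empty libraries, zero-gene annotations, multi-contig
VCFs and out-of-range coordinates raise typed errors naming the offender;
zero-length intergenic regions are omitted; nearest-marker ties break by
lower left coordinate then allele id; snap ties break to the lower
coordinate; `k` larger than the library returns one record per marker
without padding.  VCF FILTER is ignored by default (merged-caller
pipelines disagree on it) with a `pass_only` opt-in.

## Known limitations

No phage packaging-site (pac) bias or transduction-efficiency variation
between markers; no mutagen-specific mutation spectrum (ENU transition
bias); no epistasis — causativeness is per-mutation Bernoulli, and
multi-causative genomes require all causative mutations replaced at once
to revert; plate noise is a single log-normal SD with no well-position or
growth effects; features and fragments never model sequence identity, only
coordinates.
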