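"""Build a transduction plan for the candidate mutations of one mutant.

Generates a small synthetic fixture set (annotation, marker library and a
mutant VCF), then plans one transduction per candidate mutation: nearest
marker, predicted co-transduction frequency, and the number of
transductants to pick for 99% confidence of seeing at least one
replacement.
"""

import tempfile

from p1deconv import build_plan, generate_fixtures
from p1deconv.genome import GenomeMap, load_marker_table, load_variants
from p1deconv.linkage import round_half_up_percent

with tempfile.TemporaryDirectory() as tmp:
    paths = generate_fixtures(tmp, seed=42, genome_length=500_000, lam=6.0)
    genome = GenomeMap("synthetic", 500_000)
    library = load_marker_table(paths["markers"], genome)
    variants = load_variants(paths["vcf"], genome)

print(f"{len(variants)} candidate mutations, {len(library)} markers\n")
print(f"{'variant':>8} {'marker':>7} {'distance':>10} {'freq':>6} {'picks':>6}")
plan = build_plan(variants, library)
for entry in plan:
    print(f"{entry.variant_id:>8} {entry.marker_allele:>7} "
          f"{entry.distance_bp:>10,.0f} "
          f"{round_half_up_percent(entry.predicted_freq):>5}% "
          f"{entry.n_transductants:>6}")
    for other, sep, note in entry.warnings:
        print(f"         warning vs {other}: {note}")

# 'picks' is how many kanamycin-resistant transductants to screen so that,
# with 99% probability, at least one has the mutation replaced.  A warning
# means two mutations share a marker and may need the separation
# probability shown to be resolved in a single transduction.
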