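"""Look up the best marker for mapping a mutation in the packaged library.

A sequenced candidate mutation sits at some genome position; the marker
with the highest predicted co-transduction frequency is the one whose
transduction is most likely to replace the mutation with wild-type
sequence.
"""

from p1deconv import load_packaged_library, nearest_markers, wu_frequency

library = load_packaged_library()
print(f"library: {len(library)} intergenic insertions on "
      f"{library.genome.name} ({library.genome.length_bp:,} bp)")

mutation_pos = 1_474_000  # a hypothetical SNV from whole-genome sequencing
print(f"\ncandidate mutation at {mutation_pos:,} bp; three nearest markers:")
for marker, d in nearest_markers(mutation_pos, library, k=3):
    f = wu_frequency(d)
    print(f"  {marker.allele_id:>6} ({marker.strain_id})  distance {d:>9,.0f} bp"
          f"  predicted co-transduction {100 * f:5.1f}%")

# The top marker's percentage is the expected fraction of transductants in
# which the mutation has been replaced by wild-type sequence - i.e. the
# fraction of picks expected to revert the phenotype if this mutation is
# causative.
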