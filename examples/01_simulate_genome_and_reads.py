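"""Simulate a diploid genome and paired reads with known ground truth.

The generator records exactly where the two haplotypes differ, which
segments are duplicated, and where sequencing errors landed — so every
downstream estimate can be checked against the truth.
"""

from genomesurvey import GenomeSpec, ReadSimSpec, generate_genome, simulate_reads

genome = generate_genome(GenomeSpec(haploid_length=200_000, seed=1))
print(f"haploid length : {genome.length:,} bp")
print(f"realised GC    : {100 * genome.gc_fraction():.2f} %")
print(f"het sites      : {genome.het_positions.size:,} "
      f"({100 * genome.het_positions.size / genome.length:.3f} % per base)")
covered = sum(b - a for a, b in genome.repeat_intervals)
print(f"multi-copy     : {100 * covered / genome.length:.1f} % of the genome")

sim = simulate_reads(genome, ReadSimSpec(coverage=30.0, error_rate=0.003, seed=2))
total = sim.batch1.n_bases + sim.batch2.n_bases
print(f"\nread pairs     : {sim.n_pairs:,} (2 x 150 bp)")
print(f"sequenced bases: {total:,} (~{total / genome.length:.1f}x coverage)")
print(f"errors injected: {sim.n_errors:,} "
      f"({100 * sim.n_errors / total:.3f} % per base)")
# The realised per-base rates above should sit close to the requested
# het_rate (0.92%), repeat_fraction (21%), GC (45%) and error rate (0.3%).
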