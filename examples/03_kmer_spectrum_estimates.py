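"""Estimate genome size, heterozygosity and repeat content from the
17-mer depth spectrum of simulated reads, then compare with the truth.

Genome size = (total k-mer volume) / (peak depth); the revised size
removes the error k-mer volume below the spectrum's error valley.
"""

from genomesurvey import (
    GenomeSpec,
    ReadSimSpec,
    analyze_spectrum,
    count_kmers,
    generate_genome,
    simulate_reads,
)

K = 17
genome = generate_genome(GenomeSpec(haploid_length=300_000, seed=5))
coverage = 70 * 150 / (150 - K + 1)  # puts the k-mer peak near 70x
sim = simulate_reads(genome, ReadSimSpec(coverage=coverage, error_rate=0.003, seed=6))

hist = count_kmers([sim.batch1, sim.batch2], k=K)
est = analyze_spectrum(hist)

print(f"peak depth          : {est.peak_depth}x")
print(f"error valley        : depth {est.error_valley} "
      f"({100 * est.error_kmer_fraction:.2f} % of k-mer volume is error)")
print(f"genome size         : {est.genome_size / 1e6:.3f} Mbp")
print(f"revised genome size : {est.revised_genome_size / 1e6:.3f} Mbp "
      f"(truth: {genome.length / 1e6:.3f} Mbp)")
true_het = 100 * genome.het_positions.size / genome.length
true_rep = 100 * sum(b - a for a, b in genome.repeat_intervals) / genome.length
print(f"heterozygosity      : {est.het_ratio:.2f} %  (truth: {true_het:.2f} %)")
print(f"repeat ratio        : {est.repeat_ratio:.1f} %  (truth: {true_rep:.1f} %)")
# The revised size should land within a few percent of the true haploid
# length; het within ~25% relative; repeat ratio within a few points.
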