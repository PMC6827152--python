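"""GC content vs sequencing depth along an assembly, in 500 bp windows.

Depth comes from the canonical k-mer table of the read set rather than a
read aligner; contamination from another organism would show up as a
second cluster in the GC-depth plane.
"""

from genomesurvey import (
    GenomeSpec,
    ReadSimSpec,
    count_kmer_table,
    fragment_assembly,
    generate_genome,
    simulate_reads,
    summarize_gc,
    window_gc_depth,
)

genome = generate_genome(GenomeSpec(haploid_length=200_000, seed=9))
sim = simulate_reads(genome, ReadSimSpec(coverage=40.0, error_rate=0.003, seed=10))
table = count_kmer_table([sim.batch1, sim.batch2], k=17)

_contigs, scaffolds = fragment_assembly(genome, n_contigs=80, gap_length=0, seed=11)
records = window_gc_depth(scaffolds, table, window=500)
summ = summarize_gc(records)

print(f"windows          : {summ.n_windows}")
print(f"mean GC          : {summ.mean_gc:.2f} %  (genome truth: {100 * genome.gc_fraction():.2f} %)")
print(f"GC range (99 %)  : {summ.gc_low:.1f} - {summ.gc_high:.1f} %")
q1, q2, q3 = summ.depth_quartiles
print(f"depth quartiles  : {q1:.1f} / {q2:.1f} / {q3:.1f}x")
# Windows in duplicated regions sit near twice the median depth; a clean
# single-organism library shows one GC cluster around the genome mean.
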