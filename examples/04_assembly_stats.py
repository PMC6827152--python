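"""N50/N90 statistics of a fragmented assembly.

N50 is the length of the sequence at which the cumulative length of
sequences sorted longest-first reaches half the total; N90 analogous at
90%. Scaffold lengths include their N gaps by convention.
"""

from genomesurvey import GenomeSpec, compute_stats, fragment_assembly, generate_genome, stats_from_lengths

# the textbook accumulation example
s = stats_from_lengths([5, 4, 3, 2, 1])
print(f"lengths 5,4,3,2,1 -> total {s.total_length}, N50 {s.n50}, N90 {s.n90}")

genome = generate_genome(GenomeSpec(haploid_length=250_000, seed=7))
contigs, scaffolds = fragment_assembly(genome, n_contigs=120, gap_length=100, seed=8)
for label, group in (("contigs", contigs), ("scaffolds", scaffolds)):
    st = compute_stats(group)
    print(
        f"{label:9s}: n={st.total_number:4d}  total={st.total_length:,} bp  "
        f"max={st.max_length:,}  N50={st.n50:,}  N90={st.n90:,}"
    )
# Scaffolds are longer and fewer than contigs (they join contig runs with
# 100 bp N gaps), so their total length exceeds the contig total by the
# gap content and their N50 is larger.
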