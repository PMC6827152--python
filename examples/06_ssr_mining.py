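"""Mine perfect di- to hexa-nucleotide microsatellites (span >= 12 bp).

Motifs are canonicalised over rotations and strands, so TG/GT/CA/AC loci
all report as motif AC.
"""

from genomesurvey import GenomeSpec, find_ssrs, fragment_assembly, generate_genome, summarize_ssrs

demo = "TTGG" + "AC" * 7 + "GGTT" + "AGG" * 5 + "TTGG"
for r in find_ssrs(demo, sequence_id="demo"):
    print(f"  {r.sequence_id}: [{r.start},{r.end}) motif {r.motif} "
          f"({r.ssr_class}) x{r.copies}")

genome = generate_genome(GenomeSpec(haploid_length=300_000, seed=12))
_contigs, scaffolds = fragment_assembly(genome, n_contigs=100, gap_length=50, seed=13)
records = []
for rec in scaffolds:
    records.extend(find_ssrs(rec))
summary = summarize_ssrs(records)
print(f"\nSSR loci in 300 kb of random-ish sequence: {summary.total}")
for cls, count in summary.counts.items():
    print(f"  {cls:6s}: {count:4d}  ({summary.percentages[cls]:.2f} %)")
# Random sequence yields few, mostly dinucleotide, loci; real genomes are
# far richer because microsatellites expand by slippage.
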