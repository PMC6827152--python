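"""Filter paired reads and compute the sequencing quality summary.

A pair is dropped whole if either mate carries an adapter substring, too
many Ns, or too many low-quality bases; survivors are never trimmed.
"""

from genomesurvey import GenomeSpec, ReadSimSpec, generate_genome, run_qc, simulate_reads

genome = generate_genome(GenomeSpec(haploid_length=100_000, seed=3))
sim = simulate_reads(
    genome,
    ReadSimSpec(coverage=20.0, error_rate=0.003, quality_high=36, quality_low=2, seed=4),
)

clean1, clean2, stats = run_qc(sim.batch1, sim.batch2, adapter_seqs=["AGATCGGAAGAGC"])
print(f"raw bases      : {stats.raw_bases:,}")
print(f"clean bases    : {stats.clean_bases:,}")
print(f"effective rate : {stats.effective_rate:.2f} %   (clean / raw)")
print(f"error rate     : {stats.error_rate:.3f} %  (Phred-implied mean)")
print(f"Q20 / Q30      : {stats.q20:.2f} % / {stats.q30:.2f} %")
print(f"GC content     : {stats.gc_content:.2f} %")
# With the two-valued quality model Q30 equals the fraction of bases that
# were sequenced without error, so it should sit near 100*(1-0.003) = 99.7%.
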