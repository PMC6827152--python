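"""K-mer counting and spectrum-estimation checks.

Counting is verified against a string-based oracle (Biopython reverse
complement + dict counting); the estimators are verified by closed-form
identities and by parameter recovery against the simulator's ground truth.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from genomesurvey import (
    GenomeSpec,
    KmerHistogram,
    ReadSimSpec,
    analyze_spectrum,
    count_kmer_table,
    count_kmers,
    estimate_genome_size,
    estimate_het_ratio,
    estimate_repeat_ratio,
    find_error_valley,
    find_peak_depth,
    generate_genome,
    revise_genome_size,
    simulate_reads,
)
from genomesurvey._encode import revcomp

K = 17
COV_FOR_70X = 70 * 150 / (150 - K + 1)


def oracle_counts(seqs, k):
    """Independent canonical k-mer counter: pure string manipulation."""
    counts = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            counts[min(w, str(Seq(w).reverse_complement()))] += 1
    return counts


def table_to_strcounts(table):
    out = {}
    for code, depth in zip(table.codes, table.depths):
        chars = []
        c = int(code)
        for _ in range(table.k):
            chars.append("ACGT"[c & 3])
            c >>= 2
        out["".join(reversed(chars))] = int(depth)
    return out


class TestCounting:
    def test_single_read_canonical_multiset(self):
        # derived by enumerating windows of ACGTACG and canonicalizing:
        # ACG,CGT,GTA,TAC,ACG -> ACG,ACG,GTA,GTA,ACG
        table = count_kmer_table(["ACGTACG"], k=3)
        assert table_to_strcounts(table) == {"ACG": 3, "GTA": 2}

    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_matches_string_oracle_on_random_reads(self, k, rng):
        seqs = ["".join(rng.choice(list("ACGTN"), 40, p=[0.24, 0.24, 0.24, 0.24, 0.04])) for _ in range(30)]
        table = count_kmer_table(seqs, k=k)
        assert table_to_strcounts(table) == dict(oracle_counts(seqs, k))

    def test_read_and_its_revcomp_count_identically(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(10)]
        t1 = count_kmer_table(seqs, k=5)
        t2 = count_kmer_table([revcomp(s) for s in seqs], k=5)
        assert np.array_equal(t1.codes, t2.codes)
        assert np.array_equal(t1.depths, t2.depths)

    def test_volume_equals_window_count_for_nfree_reads(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), ln)) for ln in rng.integers(20, 80, 25)]
        hist = count_kmers(seqs, k=7)
        assert hist.volume == sum(len(s) - 6 for s in seqs)

    def test_windows_containing_n_are_excluded(self):
        hist = count_kmers(["ACGTNACGT"], k=3)
        # windows: ACG CGT GTN TNA NAC ACG CGT -> 4 valid instances
        assert hist.volume == 4

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            count_kmers(["ACGTACGT"], k=4)

    def test_histogram_deep_bin_preserves_volume(self):
        reads = ["ACGTACG" * 10] * 300  # heavily repeated k-mers
        full = count_kmers(reads, k=5)
        capped = count_kmer_table(reads, k=5).histogram(max_depth_tracked=10)
        assert capped.volume == full.volume


class TestValleyAndPeak:
    def test_valley_matches_bruteforce_scan(self):
        counts = {1: 10**6, 2: 10**4, 3: 500, 4: 200, 5: 150, 6: 180, 7: 400}
        counts.update({60 + d: 5000 - 100 * abs(d - 10) for d in range(20)})
        h = KmerHistogram.from_counts(17, counts)
        # brute force on the same smoothing the finder uses
        from genomesurvey.kmer import _smooth

        sm = _smooth(h.counts)
        expect = next(
            d for d in range(2, sm.size - 1) if sm[d] < sm[d - 1] and sm[d] <= sm[d + 1]
        )
        assert find_error_valley(h) == expect

    def test_monotone_histogram_has_no_error_component(self):
        h = KmerHistogram.from_counts(17, {d: 1000 + 10 * d for d in range(1, 50)})
        assert find_error_valley(h) == 1

    def test_single_spike_peak(self):
        h = KmerHistogram.from_counts(17, {70: 12345})
        assert find_peak_depth(h, valley=1) == 70

    def test_no_peak_above_valley_raises(self):
        h = KmerHistogram.from_counts(17, {1: 100, 2: 10})
        with pytest.raises(ValueError):
            find_peak_depth(h, valley=10)

    def test_error_free_simulation_valley_is_one(self, plain_reads):
        h = count_kmers([plain_reads.batch1, plain_reads.batch2], k=K)
        assert find_error_valley(h) == 1

    def test_error_spectrum_valley_between_spike_and_peak(self, survey_reads):
        h = count_kmers([survey_reads.batch1, survey_reads.batch2], k=K)
        v = find_error_valley(h)
        assert 1 < v < 35

    def test_peak_matches_target_kmer_depth(self, plain_reads):
        # coverage 50 -> expected k-mer depth 50*(150-17+1)/150 = 44.7
        h = count_kmers([plain_reads.batch1, plain_reads.batch2], k=K)
        peak = find_peak_depth(h, find_error_valley(h))
        assert abs(peak - 44.7) <= 1.5

    def test_high_het_returns_full_depth_peak(self):
        g = generate_genome(
            GenomeSpec(haploid_length=150_000, het_rate=0.02, repeat_fraction=0.0, seed=41)
        )
        sim = simulate_reads(g, ReadSimSpec(coverage=COV_FOR_70X, error_rate=0.0, seed=43))
        h = count_kmers([sim.batch1, sim.batch2], k=K)
        peak = find_peak_depth(h, find_error_valley(h))
        assert abs(peak - 70) <= 7  # full-depth peak, not ~35


class TestSizeFormulas:
    def test_division_identity(self):
        assert estimate_genome_size(1000, 10) == 100.0

    def test_output_times_peak_recovers_volume_to_ulp(self):
        vol = 36_648_430_961
        size = estimate_genome_size(vol, 70)
        assert size * 70 == pytest.approx(vol, rel=1e-15)

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError):
            estimate_genome_size(1000, 0)

    def test_revision_identity_and_arithmetic(self):
        assert revise_genome_size(500.0, 0.0) == 500.0
        assert revise_genome_size(523.55e6, 0.02874) == pytest.approx(508.503e6, rel=1e-4)
        with pytest.raises(ValueError):
            revise_genome_size(1.0, 1.0)

    def test_simple_genome_size_within_two_percent(self, plain_reads, plain_genome):
        h = count_kmers([plain_reads.batch1, plain_reads.batch2], k=K)
        est = analyze_spectrum(h)
        assert est.revised_genome_size == est.genome_size  # error-free
        assert abs(est.genome_size - plain_genome.length) / plain_genome.length < 0.02


class TestHetAndRepeat:
    def test_het_free_simulation_near_zero(self, plain_reads):
        h = count_kmers([plain_reads.batch1, plain_reads.batch2], k=K)
        v = find_error_valley(h)
        p = find_peak_depth(h, v)
        assert estimate_het_ratio(h, p, v) < 0.05

    def test_repeat_free_simulation_near_zero(self, plain_reads):
        h = count_kmers([plain_reads.batch1, plain_reads.batch2], k=K)
        v = find_error_valley(h)
        p = find_peak_depth(h, v)
        assert estimate_repeat_ratio(h, p, v) < 2.0

    def test_het_estimates_strictly_ordered(self):
        vals = []
        for het in (0.003, 0.012):
            g = generate_genome(
                GenomeSpec(haploid_length=150_000, het_rate=het, repeat_fraction=0.15, seed=47)
            )
            sim = simulate_reads(g, ReadSimSpec(coverage=COV_FOR_70X, error_rate=0.003, seed=53))
            h = count_kmers([sim.batch1, sim.batch2], k=K)
            vals.append(analyze_spectrum(h).het_ratio)
        assert vals[0] < vals[1]

    def test_repeat_estimate_increases_with_repeat_fraction(self):
        vals = []
        for rep in (0.10, 0.20):
            g = generate_genome(
                GenomeSpec(haploid_length=150_000, het_rate=0.0092, repeat_fraction=rep, seed=59)
            )
            sim = simulate_reads(g, ReadSimSpec(coverage=COV_FOR_70X, error_rate=0.003, seed=61))
            h = count_kmers([sim.batch1, sim.batch2], k=K)
            vals.append(analyze_spectrum(h).repeat_ratio)
        assert vals[0] < vals[1]

    def test_valley_at_or_above_peak_rejected(self):
        h = KmerHistogram.from_counts(17, {d: 100 for d in range(1, 80)})
        with pytest.raises(ValueError):
            estimate_het_ratio(h, peak_depth=10, valley=10)
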