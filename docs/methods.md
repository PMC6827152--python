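# Methods

This note documents the models, estimators and numerical choices behind
`genomesurvey`, and what the synthetic-data validation does and does not
demonstrate.

## K-mer spectrum model

All spectrum estimates derive from the depth histogram of **canonical
k-mers** (the lexicographically smaller of a k-mer and its reverse
complement; k odd so no k-mer is its own reverse complement; default
k = 17). Counting is exact: every N-free window contributes one instance,
encoded as a 2k-bit integer; depths come from sorting the full code array.
At the scales this package targets in-memory exact counting is cheap, and
it keeps every downstream number bit-reproducible. Externally produced
histograms (e.g. Jellyfish `histo` output) can be analysed through the
same TSV interface.

For a diploid genome of haploid length G sequenced to per-k-mer depth λ
(λ = coverage × (L_r − k + 1)/L_r for read length L_r), distinct k-mers
fall into depth components:

| component | depth | origin |
|---|---|---|
| error | ~1 | k-mers created by sequencing errors |
| heterozygous | λ/2 | a het site yields one distinct k-mer per haplotype |
| homozygous single-copy | λ | identical on both haplotypes |
| heterozygous two-copy | 3λ/2 | two-copy k-mer whose partner haplotype carries a variant |
| homozygous two-copy | 2λ | exact repeats present twice per haplotype |

### Error valley and peak

Extremum detection runs on a centred 3-bin moving average of the counts.
The **error valley** is the smallest depth d ≥ 2 with sm[d] < sm[d−1] and
sm[d] ≤ sm[d+1]; a candidate is only accepted when the spike to its left
actually dominates the main peak to its right, otherwise the histogram has
no error component and the valley is reported as 1 (in which case the
error fraction is 0 and the revised size equals the unrevised size — the
handful of depth-1 k-mers produced by coverage ramp-down at sequence ends
are not error mass).

The **peak** is the highest smoothed local maximum above the valley, with
ties broken toward the lower depth. At high heterozygosity the λ/2
component can out-mass the homozygous peak; if another local maximum sits
at 1.8–2.2× the argmax depth with at least 40% of its smoothed height, the
argmax is taken to be the half-depth peak and the 2× maximum is returned.
The threshold separates this case from a repeat harmonic at 2λ, whose
height is far below 40% of the main peak for repeat fractions in the
survey-realistic range (≲ 30%).

### Genome size

`genome_size = volume / peak_depth` (real division; display layers round
Mbp to 2 decimals), and `revised = genome_size × (1 − e)` with *e* the
k-mer volume at or below the error valley divided by total volume. This
reading of the "error rate" — the error k-mer volume fraction, not the
per-base error rate — is the only one that makes the revision
self-consistent: the numerator of the size formula is inflated by exactly
the error k-mer volume.

### Mixture fit

Component weights (A, B, D, C) at means (λ/2, λ, 3λ/2, 2λ) are estimated
by non-negative least squares on the raw counts over depths
(valley, 2.5λ]:

- λ is refined from the integer peak bin to the count-weighted centroid of
  a symmetric ±2σ window, iterated three times. Symmetry matters: an
  asymmetric window biases λ low by a sub-bin offset, and the resulting
  right-flank residual masquerades as a 3λ/2 component.
- Each basis is a negative-binomial pmf with a common dispersion factor
  φ = var/mean chosen from a small grid (1.0–1.3) by residual; φ = 1 is
  Poisson. Real read sampling is slightly overdispersed (mate-overlap
  double counting, end effects), and fitting φ prevents that dispersion
  from being misread as repeat mass.

### Heterozygosity

Let a = A/(A+B), the heterozygous share of distinct single-copy k-mers.
Under the biallelic-SNV model, a het locus contributes **two** distinct
half-depth k-mers where a homozygous locus contributes one full-depth
k-mer, so with h = P(a k-window covers ≥ 1 het site):

    a = 2h / (1 + h)   ⇒   h = a / (2 − a),
    het = 1 − (1 − h)^(1/k).

This exact inversion (rather than the small-a linearisation het ≈ a/2k)
stays accurate at survey-realistic heterozygosities around 1%, where
h ≈ 0.15 is no longer small. Restricting the ratio to A and B keeps
two-copy k-mers (D, C) out of the numerator and denominator, so the
estimate is insensitive to repeat content. Degenerate fits (A + B = 0)
return 0.

### Repeat ratio

Two-copy components are converted to genome (locus) fractions by weighting
each component with its copy-depth multiple:

    repeat_ratio = (1.5·D + 2·C) / (0.5·A + B + 1.5·D + 2·C).

Volume beyond the fit window (depth > 2.5λ, i.e. higher-order repeats) is
added to both numerator and denominator as locus-equivalents
(volume / λ). A simpler volume-above-threshold rule (everything deeper
than 2λ − valley) systematically undercounts — by the Poisson tail below
the threshold, and by the 3λ/2 class that heterozygosity splits off the
two-copy peak — recovering only ~half the true repeat fraction at 1%
heterozygosity; the mixture attribution recovers within ~2 points.

## Read QC

A read **pair** is dropped whole (never orphaned, to keep k-mer coverage
unbiased) if either mate contains a supplied adapter as an exact
substring, has an N fraction above 0.1, or has more than half its bases
below Phred 5. Defaults follow common survey practice and are
configurable; surviving reads are not trimmed. Reported statistics:
effective rate = 100·clean/raw bases; error rate = mean of 10^(−Q/10);
Q20/Q30 = percent of bases at ≥ 99% / ≥ 99.9% implied accuracy; GC over
unambiguous bases only.

## Assembly statistics

Lengths sorted descending; N50 (N90) is the length of the first sequence
at which the running sum reaches ≥ 50% (90%) of the total — "reached"
means ≥, so ties among equal lengths are harmless. Scaffold lengths count
N gap characters by default (`count_n_in_length=False` to exclude them).
Zero-length records are skipped with a warning.

## GC–depth profile

Windows (default 500 bp) tile each assembly sequence without overlap; a
trailing remainder shorter than half a window merges into the previous
window. Per window: GC percent over A/C/G/T bases, and the mean depth of
the window's N-free canonical k-mers looked up in the k-mer table of the
read set. Using k-mer depth instead of alignment is a deliberate proxy —
the profile is a QC visualisation, k-mer depth tracks read depth closely
(expected depth = coverage × (L_r−k+1)/L_r), and it keeps the package free
of an aligner. The summary reports the window-length-weighted mean GC, the
0.5th–99.5th percentile GC range and depth quartiles.

## SSR mining

A locus is a maximal perfect tandem run of a primitive unit of length 2–6
whose span of complete copies is ≥ 12 bp (hence ≥ 6/4/3/3/2 copies for
di- through hexa-nucleotides; a partial trailing copy never counts).
Mononucleotide runs are excluded. Maximality is defined on the periodic
region: the run cannot be extended by even one period-preserving base on
either side, and complete copies are counted from the region's left end.
This makes phase-shifted sub-runs unreportable and guarantees that two
same-unit-length records never share a complete copy (adjacent runs
separated by a single period-breaking base may share up to unit_length − 1
boundary bases — both are genuinely maximal). Runs containing N are split
at the N. Motifs are canonicalised to the smallest rotation over both
strands, and units that are powers of a shorter unit are classified by
their primitive root. The scanner is validated against a brute-force
oracle that tests every (start, unit length) by direct string comparison.

## Synthetic data: what it does and does not emulate

The generator draws i.i.d. bases at the requested GC; repeats are **exact
duplications** of donor slots (default 500 bp) into target slots, with
both donor and copy recorded, so the requested repeat fraction equals the
multi-copy fraction of the genome and two-copy k-mers sit at exactly twice
the peak. Haplotype B differs from A by i.i.d. biallelic substitutions at
the requested per-base rate. Reads are uniform 2×150 bp pairs (Gaussian
insert 350 ± 35 bp — the library SD is a free choice at 10% of the mean)
with uniform substitution errors and a two-valued quality string (high for
correct, low for erroneous bases). Defaults mirror a survey-style subject:
GC 45%, heterozygosity 0.92%, 21% repeat content, 0.3% error rate.

Deliberately not modelled: indels and structural variation, diverged or
nested repeat families, PCR duplicates, adapter read-through (QC tests
inject adapters explicitly), position-dependent quality, coverage bias
with GC. Passing parameter recovery therefore shows the estimators are
correct **under the stated generative model** — exact-copy repeats and
SNV-only heterozygosity — not that they are robust to diverged repeats or
indel-rich genomes, where k-mer-based repeat and heterozygosity estimates
are known to blur.

## Problem sizes and determinism

The validation suite simulates 60–300 kb genomes for per-module checks and
a 1 Mb genome at ~70× k-mer depth for end-to-end parameter recovery —
sizes chosen so the whole suite completes in a couple of minutes while
leaving every depth component well populated (a 1 Mb genome yields ~7×10⁷
17-mer instances, ample for the mixture fit). All randomness flows through
seeded `numpy` generators; identical (spec, seed) inputs produce
byte-identical FASTQ/FASTA outputs, and the pipeline report is identical
across reruns up to its provenance timestamp.

## Known limitations

- The error valley is a hard volume cut; error k-mers above the valley
  (recurrent errors) inflate the revised size slightly, genomic k-mers
  below it (coverage dips) deflate it. At 0.3% error and 70× the net bias
  is under 1%.
- Heterozygosity and repeat estimates assume diploidy and a single
  coverage mode; polyploids and strongly contaminated libraries violate
  the mixture.
- The integer peak depth is what the size formula divides by (matching the
  conventional report format); at low coverage the sub-bin offset can
  contribute ~1% size error.
- SSR counts depend on the maximality convention; tools differ in how they
  resolve compound and phase-shifted runs, so absolute counts are
  comparable only under identical rules.
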