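"""Canonical k-mer counting and k-mer-spectrum genome profiling.

The survey estimators all derive from the depth histogram of canonical
k-mers (k odd, default 17) counted over the clean reads:

* genome size      = total k-mer volume / homozygous peak depth,
* revised size     = genome size x (1 - error k-mer volume fraction),
* heterozygosity   from the weight of the half-depth (lambda/2) component,
* repeat ratio     from the k-mer volume beyond the two-copy threshold.

Counting is exact: every N-free window of length k contributes the
lexicographically smaller of itself and its reverse complement, encoded as
a 2k-bit integer; depths come from sorting the code array. No probabilistic
sketches — at survey-test scale (tens of millions of k-mers) exact counting
is cheap and keeps every downstream number reproducible to the byte.

Model of the histogram
----------------------
For a diploid genome sequenced to per-k-mer depth lambda, distinct k-mers
fall into components that are Poisson-shaped around

* lambda/2 : k-mers overlapping a heterozygous site (one per haplotype),
* lambda   : homozygous single-copy k-mers,
* 2*lambda : two-copy (repeat) k-mers,
* depth ~1 : k-mers created by sequencing errors (the low-depth spike).

The error valley is the first local minimum separating the spike from the
main peak; everything at or below it counts as error volume. Peak and
valley detection run on a centred 3-bin moving average of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.stats import nbinom, poisson

from ._encode import encode
from .io import ReadBatch

__all__ = [
    "KmerTable",
    "KmerHistogram",
    "SpectrumEstimate",
    "count_kmer_table",
    "count_kmers",
    "find_error_valley",
    "find_peak_depth",
    "estimate_genome_size",
    "revise_genome_size",
    "estimate_het_ratio",
    "estimate_repeat_ratio",
    "analyze_spectrum",
]

DEFAULT_K = 17
DEFAULT_MAX_DEPTH = 10_000


def _validate_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical form is ill-defined for palindromes)")
    if not 3 <= k <= 31:
        raise ValueError("k must be in [3, 31]")


def _canonical_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Canonical 2-bit codes of all N-free length-k windows of ``arr``.

    ``arr`` holds base codes 0-3 with >=4 marking N or a read separator.
    """
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    isn = arr > 3
    cs = np.zeros(arr.size + 1, dtype=np.int64)
    np.cumsum(isn, out=cs[1:])
    ok = (cs[k:] - cs[:-k]) == 0
    av = np.where(isn, 0, arr).astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for j in range(k):
        col = av[j : j + n]
        fwd = (fwd << 2) | col
        rev |= (3 - col) << (2 * j)
    return np.minimum(fwd, rev)[ok]


def _iter_seqs(reads) -> Iterable[str]:
    if isinstance(reads, ReadBatch):
        return reads.seqs
    if isinstance(reads, str):
        return [reads]
    out: list[str] = []
    for item in reads:
        if isinstance(item, ReadBatch):
            out.extend(item.seqs)
        else:
            out.append(item)
    return out


@dataclass
class KmerTable:
    """Sorted distinct canonical k-mer codes with their depths."""

    k: int
    codes: np.ndarray  # int64, sorted ascending
    depths: np.ndarray  # int64, same length

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def volume(self) -> int:
        return int(self.depths.sum())

    def depth_of(self, codes: np.ndarray) -> np.ndarray:
        """Depths for query canonical codes; absent k-mers get 0."""
        idx = np.searchsorted(self.codes, codes)
        idx = np.clip(idx, 0, self.codes.size - 1)
        hit = self.codes.size > 0
        out = np.zeros(codes.size, dtype=np.int64)
        if hit:
            found = self.codes[idx] == codes
            out[found] = self.depths[idx[found]]
        return out

    def histogram(self, max_depth_tracked: int = DEFAULT_MAX_DEPTH) -> "KmerHistogram":
        if self.depths.size == 0:
            return KmerHistogram(self.k, np.zeros(2, dtype=np.int64), max_depth_tracked, 0)
        cap = max_depth_tracked
        clipped = np.minimum(self.depths, cap)
        counts = np.bincount(clipped)
        # if anything was clipped, carry the final bin's exact instance
        # volume separately so volume accounting stays exact
        deep_volume = 0
        if (self.depths > cap).any():
            deep_volume = int(self.depths[self.depths >= cap].sum())
        return KmerHistogram(self.k, counts.astype(np.int64), cap, deep_volume)


@dataclass
class KmerHistogram:
    """Depth histogram: ``counts[d]`` = distinct canonical k-mers at depth d.

    Depths above ``max_depth_tracked`` collapse into the final bin; their
    exact instance volume is kept in ``deep_volume`` so that
    :attr:`volume` equals the total number of counted k-mer instances.
    """

    k: int
    counts: np.ndarray  # int64, counts[0] == 0
    max_depth_tracked: int = DEFAULT_MAX_DEPTH
    deep_volume: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size and self.counts[0] != 0:
            raise ValueError("depth-0 bin must be empty")
        if (self.counts < 0).any():
            raise ValueError("negative histogram count")

    @property
    def max_depth(self) -> int:
        return int(self.counts.size - 1)

    @property
    def volume(self) -> int:
        d = np.arange(self.counts.size, dtype=np.int64)
        vol = int((d * self.counts).sum())
        if self.deep_volume:
            vol += self.deep_volume - self.max_depth_tracked * int(
                self.counts[self.max_depth_tracked]
            )
        return vol

    def volume_at_most(self, depth: int) -> int:
        depth = min(depth, self.max_depth)
        d = np.arange(depth + 1, dtype=np.int64)
        return int((d * self.counts[: depth + 1]).sum())

    def volume_above(self, depth: int) -> int:
        return self.volume - self.volume_at_most(depth)

    @classmethod
    def from_counts(cls, k: int, counts: dict[int, int]) -> "KmerHistogram":
        """Build from a {depth: count} mapping (e.g. hand-written fixtures)."""
        if not counts:
            return cls(k, np.zeros(2, dtype=np.int64))
        arr = np.zeros(max(counts) + 1, dtype=np.int64)
        for d, c in counts.items():
            if d < 1:
                raise ValueError("depths must be >= 1")
            arr[d] = c
        return cls(k, arr)

    def to_tsv(self, path: str | Path) -> None:
        """Write 2-column depth<TAB>count (Jellyfish ``histo`` style)."""
        with open(path, "w") as fh:
            for d in range(1, self.counts.size):
                if self.counts[d]:
                    fh.write(f"{d}\t{int(self.counts[d])}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int = DEFAULT_K) -> "KmerHistogram":
        counts: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                d, c = line.split()[:2]
                counts[int(d)] = int(c)
        return cls.from_counts(k, counts)


def count_kmer_table(reads, k: int = DEFAULT_K, chunk_bases: int = 8_000_000) -> KmerTable:
    """Exact canonical k-mer counts over reads (ReadBatch(es) or strings)."""
    _validate_k(k)
    seqs = _iter_seqs(reads)
    code_chunks: list[np.ndarray] = []
    buf: list[str] = []
    size = 0

    def flush() -> None:
        nonlocal size
        if not buf:
            return
        arr = encode("N".join(buf))
        codes = _canonical_codes(arr, k)
        if codes.size:
            code_chunks.append(codes)
        buf.clear()
        size = 0

    for s in seqs:
        buf.append(s)
        size += len(s)
        if size >= chunk_bases:
            flush()
    flush()
    if not code_chunks:
        all_codes = np.empty(0, dtype=np.int64)
    else:
        all_codes = np.concatenate(code_chunks)
    uniq, depths = np.unique(all_codes, return_counts=True)
    return KmerTable(k=k, codes=uniq, depths=depths.astype(np.int64))


def count_kmers(reads, k: int = DEFAULT_K, max_depth_tracked: int = DEFAULT_MAX_DEPTH) -> KmerHistogram:
    """Depth histogram of canonical k-mers (see :func:`count_kmer_table`)."""
    return count_kmer_table(reads, k).histogram(max_depth_tracked)


def _smooth(counts: np.ndarray) -> np.ndarray:
    """Centred 3-bin moving average over depths >= 1 (edges truncated)."""
    x = counts.astype(np.float64)
    x[0] = 0.0
    body = x[1:]
    kern = np.ones(3)
    num = np.convolve(body, kern, mode="same")
    den = np.convolve(np.ones_like(body), kern, mode="same")
    out = np.zeros_like(x)
    out[1:] = num / den
    return out


def find_error_valley(h: KmerHistogram) -> int:
    """First local minimum after the low-depth error spike; 1 if no spike.

    Scans the 3-bin-smoothed counts for the smallest depth d >= 2 with
    sm[d] < sm[d-1] and sm[d] <= sm[d+1]. A candidate only counts as an
    error valley if the spike to its left actually dominates the main peak
    to its right (otherwise the histogram has no error component and the
    valley is reported as 1).
    """
    sm = _smooth(h.counts)
    if sm.size < 4:
        return 1
    valley = None
    for d in range(2, sm.size - 1):
        if sm[d] < sm[d - 1] and sm[d] <= sm[d + 1]:
            valley = d
            break
    if valley is None:
        return 1
    spike = sm[1 : valley + 1].max()
    peak = sm[valley + 1 :].max() if valley + 1 < sm.size else 0.0
    if spike <= peak:
        return 1
    return valley


def _local_maxima(sm: np.ndarray, lo: int) -> list[int]:
    out = []
    for d in range(max(lo, 1), sm.size):
        left = sm[d - 1] if d - 1 >= 0 else -np.inf
        right = sm[d + 1] if d + 1 < sm.size else -np.inf
        if sm[d] >= left and sm[d] >= right and sm[d] > 0:
            out.append(d)
    return out


def find_peak_depth(h: KmerHistogram, valley: int, het_ratio_threshold: float = 0.4) -> int:
    """Depth of the homozygous coverage peak.

    The raw argmax above the valley can be the heterozygous half-depth
    (lambda/2) component when heterozygosity is high. If another local
    maximum sits at ~2x the argmax depth with at least
    ``het_ratio_threshold`` of its (smoothed) height, the argmax is taken
    to be that half-depth peak and the 2x maximum is returned instead.
    A repeat harmonic at 2*lambda is far smaller than this threshold, so
    the rule never promotes it. Ties break toward the lower depth.
    """
    sm = _smooth(h.counts)
    cands = _local_maxima(sm, valley + 1)
    cands = [d for d in cands if d > valley]
    if not cands:
        raise ValueError("no peak above the error valley")
    gm = max(cands, key=lambda d: (sm[d], -d))
    doubles = [d for d in cands if 1.8 * gm <= d <= 2.2 * gm and sm[d] >= het_ratio_threshold * sm[gm]]
    if doubles:
        return max(doubles, key=lambda d: (sm[d], -d))
    return gm


def estimate_genome_size(kmer_number: float, peak_depth: int) -> float:
    """Genome size in bases: total k-mer volume / peak depth (real division)."""
    if peak_depth < 1:
        raise ValueError("peak depth must be >= 1")
    return kmer_number / peak_depth


def revise_genome_size(genome_size: float, error_kmer_fraction: float) -> float:
    """Shrink the estimate by the error k-mer volume fraction."""
    if not 0.0 <= error_kmer_fraction < 1.0:
        raise ValueError("error_kmer_fraction must be in [0, 1)")
    return genome_size * (1.0 - error_kmer_fraction)


def _component_weights(
    h: KmerHistogram, peak_depth: int, valley: int
) -> tuple[float, float, float, float]:
    """Non-negative LS weights of the Poisson mixture at depths
    (lambda/2, lambda, 3*lambda/2, 2*lambda).

    Fit over depths (valley, 2.5*lambda]: each basis is a Poisson pmf in
    depth; the weights estimate the number of distinct k-mers in the
    heterozygous, homozygous single-copy, heterozygous two-copy (a
    two-copy k-mer whose partner haplotype carries a variant sits at
    3*lambda/2) and homozygous two-copy components.

    ``peak_depth`` is an integer bin; the components are centred on the
    sub-bin mean depth (count-weighted centroid within +/-20% of the
    peak), otherwise the fractional offset between the integer peak and
    the true mean leaks into the 1.5*lambda component and inflates the
    repeat weight.
    """
    # sub-bin peak mean: iterated count-weighted centroid over a symmetric
    # +/- 2 sigma window (asymmetric truncation would bias lambda low)
    lam = float(peak_depth)
    for _ in range(3):
        sd = np.sqrt(lam)
        lo_c = max(int(np.floor(lam - 2 * sd)), valley + 1)
        hi_c = min(int(np.ceil(lam + 2 * sd)), h.max_depth)
        dc = np.arange(lo_c, hi_c + 1)
        wc = h.counts[lo_c : hi_c + 1].astype(np.float64)
        if wc.sum() <= 0:
            lam = float(peak_depth)
            break
        lam = float((dc * wc).sum() / wc.sum())
    hi = min(int(round(2.5 * lam)), h.max_depth)
    d = np.arange(valley + 1, hi + 1)
    if d.size < 4:
        raise ValueError("histogram too narrow to fit mixture components")
    y = h.counts[valley + 1 : hi + 1].astype(np.float64)

    def pmf(depths: np.ndarray, mean: float, phi: float) -> np.ndarray:
        if phi <= 1.0:
            return poisson.pmf(depths, mean)
        r = mean / (phi - 1.0)
        return nbinom.pmf(depths, r, 1.0 / phi)

    # real read sampling is slightly overdispersed relative to Poisson
    # (mate-overlap double counting, coverage ramp at sequence ends); fit
    # the dispersion factor var/mean from the data over a small grid so
    # that dispersion is not misread as a 1.5*lambda repeat component
    best: tuple[float, np.ndarray] | None = None
    for phi in (1.0, 1.02, 1.05, 1.1, 1.15, 1.2, 1.3):
        basis = np.column_stack(
            [
                pmf(d, lam / 2.0, phi),
                pmf(d, lam, phi),
                pmf(d, 1.5 * lam, phi),
                pmf(d, 2.0 * lam, phi),
            ]
        )
        w, resid = nnls(basis, y)
        if best is None or resid < best[0]:
            best = (resid, w)
    w = best[1]
    return float(w[0]), float(w[1]), float(w[2]), float(w[3])


def estimate_het_ratio(
    h: KmerHistogram, peak_depth: int, valley: int, k: int | None = None
) -> float:
    """Per-base heterozygosity in percent from the half-depth component.

    With a = A/(A+B) the heterozygous share of distinct single-copy k-mers
    (A at lambda/2, B at lambda), each heterozygous locus contributes two
    distinct half-depth k-mers against one full-depth k-mer for a
    homozygous locus, so a = 2h/(1+h) where h is the probability that a
    k-window covers at least one heterozygous site. Inverting and
    converting the window rate to a per-base rate:

        h = a / (2 - a),    het = 1 - (1 - h)^(1/k).
    """
    if k is None:
        k = h.k
    if valley >= peak_depth:
        raise ValueError("valley must lie below the peak")
    A, B, _D, _C = _component_weights(h, peak_depth, valley)
    if A + B <= 0:
        return 0.0
    a = A / (A + B)
    hwin = a / (2.0 - a)
    hwin = min(max(hwin, 0.0), 1.0 - 1e-12)
    return 100.0 * (1.0 - (1.0 - hwin) ** (1.0 / k))


def estimate_repeat_ratio(h: KmerHistogram, peak_depth: int, valley: int) -> float:
    """Percent of genomic k-mer volume attributable to multi-copy sequence.

    The mixture fit attributes the distinct k-mers at 3*lambda/2 (weight D)
    and 2*lambda (weight C) to two-copy loci; their volume share relative
    to all fitted genomic volume,

        (1.5*D + 2*C) / (0.5*A + B + 1.5*D + 2*C),

    estimates the fraction of the genome in multi-copy sequence. Volume
    beyond the fit window (deeper than ~2.5*lambda: higher-order repeats)
    is added to the numerator and denominator directly, so high-copy
    k-mers still count as repeat mass. A plain volume-above-threshold rule
    undercounts by the Poisson tail and by the half-depth split that
    heterozygous sites impose on two-copy k-mers; the fit restores both.
    """
    if valley >= peak_depth:
        raise ValueError("valley must lie below the peak")
    A, B, D, C = _component_weights(h, peak_depth, valley)
    genomic = 0.5 * A + B + 1.5 * D + 2.0 * C
    if genomic <= 0:
        return 0.0
    hi = min(int(round(2.5 * peak_depth)), h.max_depth)
    beyond = h.volume_above(hi) / peak_depth  # locus-equivalents past the window
    multi = 1.5 * D + 2.0 * C + beyond
    return 100.0 * multi / (genomic + beyond)


@dataclass
class SpectrumEstimate:
    """One row of survey estimates derived from a k-mer histogram."""

    k: int
    peak_depth: int
    kmer_number: int
    error_valley: int
    error_kmer_fraction: float
    genome_size: float  # bases
    revised_genome_size: float  # bases
    het_ratio: float  # percent
    repeat_ratio: float  # percent

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "peak_depth": self.peak_depth,
            "kmer_number": self.kmer_number,
            "error_valley": self.error_valley,
            "error_kmer_fraction": self.error_kmer_fraction,
            "genome_size": self.genome_size,
            "genome_size_mbp": round(self.genome_size / 1e6, 2),
            "revised_genome_size": self.revised_genome_size,
            "revised_genome_size_mbp": round(self.revised_genome_size / 1e6, 2),
            "het_ratio": self.het_ratio,
            "repeat_ratio": self.repeat_ratio,
        }


def analyze_spectrum(h: KmerHistogram) -> SpectrumEstimate:
    """Full spectrum analysis: valley, peak, sizes, het and repeat ratios."""
    valley = find_error_valley(h)
    peak = find_peak_depth(h, valley)
    vol = h.volume
    # valley == 1 means "no error component": nothing to revise away
    err_frac = h.volume_at_most(valley) / vol if vol and valley > 1 else 0.0
    size = estimate_genome_size(vol, peak)
    revised = revise_genome_size(size, err_frac)
    het = estimate_het_ratio(h, peak, valley)
    rep = estimate_repeat_ratio(h, peak, valley)
    return SpectrumEstimate(
        k=h.k,
        peak_depth=peak,
        kmer_number=vol,
        error_valley=valley,
        error_kmer_fraction=err_frac,
        genome_size=size,
        revised_genome_size=revised,
        het_ratio=het,
        repeat_ratio=rep,
    )
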