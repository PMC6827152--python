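"""Synthetic diploid genomes and error-bearing paired reads.

Every downstream stage of the survey (QC, k-mer spectrum, assembly
statistics, GC-depth, SSR mining) is validated by parameter recovery
against this generator, so the generator carries explicit ground truth:
heterozygous positions, duplicated intervals and fragment coordinates are
all recorded and sufficient to compute the true heterozygosity, repeat
fraction and per-base error rate without re-inference.

Model choices
-------------
* Heterozygous sites are biallelic substitutions (no indels), placed i.i.d.
  per base at rate ``het_rate``; this mirrors how a per-base heterozygosity
  percentage is reported for survey data and keeps k-mer theory exact.
* Repeats are exact duplications: the genome is tiled into slots of
  ``repeat_unit_length`` and donor→target slot pairs are overwritten until
  the requested fraction of the genome is multi-copy. Both donor and copy
  are recorded in ``repeat_intervals``, so the intervals cover
  ``repeat_fraction`` of the genome and the expected multi-copy k-mer depth
  is exactly twice the main peak.
* Sequencing errors are uniform substitutions; qualities are two-valued
  (``quality_high`` for correct bases, ``quality_low`` for erroneous ones),
  which is sufficient for Q20/Q30 accounting.

All coordinates are 0-based half-open. Identical (spec, seed) inputs
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._encode import CODE_TO_BASE, decode, encode
from .io import PHRED_OFFSET, ReadBatch

__all__ = [
    "GenomeSpec",
    "DiploidGenome",
    "ReadSimSpec",
    "SimulatedReads",
    "generate_genome",
    "simulate_reads",
    "fragment_assembly",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Ground-truth parameters of a synthetic diploid genome.

    Defaults emulate a small-scale analogue of a ~500 Mb marine teleost
    survey genome: GC 45%, per-base heterozygosity 0.92%, 21% of the genome
    in multi-copy sequence.
    """

    haploid_length: int = 1_000_000
    gc_fraction: float = 0.45
    repeat_fraction: float = 0.21
    repeat_unit_length: int = 500
    het_rate: float = 0.0092
    seed: int = 0

    def __post_init__(self) -> None:
        if self.haploid_length <= 0:
            raise ValueError("haploid_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ValueError("repeat_fraction must be in [0, 1)")
        if not 0.0 <= self.het_rate <= 0.05:
            raise ValueError("het_rate must be in [0, 0.05]")
        if self.repeat_fraction > 0:
            if self.repeat_unit_length <= 0:
                raise ValueError("repeat_unit_length must be positive")
            if self.haploid_length < 10 * self.repeat_unit_length:
                raise ValueError(
                    "haploid_length must be >= 10 * repeat_unit_length "
                    "when repeat_fraction > 0"
                )


@dataclass
class DiploidGenome:
    """Two haplotypes of equal length plus the generator's ground truth."""

    a_codes: np.ndarray  # uint8, haplotype A
    b_codes: np.ndarray  # uint8, haplotype B
    het_positions: np.ndarray  # sorted 0-based positions where A != B
    repeat_intervals: list[tuple[int, int]]  # disjoint [start, end) on A
    spec: GenomeSpec

    @property
    def length(self) -> int:
        return int(self.a_codes.size)

    @property
    def haplotype_a(self) -> str:
        return decode(self.a_codes)

    @property
    def haplotype_b(self) -> str:
        return decode(self.b_codes)

    def gc_fraction(self) -> float:
        gc = np.count_nonzero((self.a_codes == 1) | (self.a_codes == 2))
        return gc / self.length


def generate_genome(spec: GenomeSpec) -> DiploidGenome:
    """Draw a diploid genome with known GC, repeat and heterozygosity truth.

    Base composition is i.i.d. with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2.
    Repeats are installed first on haplotype A; haplotype B is then derived
    by flipping each base independently with probability ``het_rate`` to a
    uniformly chosen different base.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.haploid_length
    g = spec.gc_fraction
    probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    a = rng.choice(4, size=L, p=probs).astype(np.uint8)

    repeat_intervals: list[tuple[int, int]] = []
    if spec.repeat_fraction > 0:
        u = spec.repeat_unit_length
        n_slots = L // u
        n_events = int(round(spec.repeat_fraction * L / (2 * u)))
        if n_events < 1:
            raise ValueError("repeat_fraction too small to place one duplication")
        if 2 * n_events > n_slots:
            raise ValueError("repeat_fraction infeasible at this unit length")
        slots = rng.permutation(n_slots)[: 2 * n_events]
        donors, targets = slots[:n_events], slots[n_events:]
        for d, t in zip(donors, targets):
            a[t * u : (t + 1) * u] = a[d * u : (d + 1) * u]
        repeat_intervals = sorted(
            (int(s) * u, (int(s) + 1) * u) for s in slots
        )

    b = a.copy()
    het_positions = np.array([], dtype=np.int64)
    if spec.het_rate > 0:
        mask = rng.random(L) < spec.het_rate
        het_positions = np.flatnonzero(mask)
        shift = rng.integers(1, 4, size=het_positions.size).astype(np.uint8)
        b[het_positions] = (a[het_positions] + shift) % 4

    return DiploidGenome(a, b, het_positions, repeat_intervals, spec)


@dataclass(frozen=True)
class ReadSimSpec:
    """Paired-end sequencing model: fragment sizes, coverage, error rate.

    ``coverage`` is total sequenced bases divided by the haploid length
    (both haplotypes are sampled with equal probability, so each haplotype
    sees coverage/2). The resulting k-mer peak depth for homozygous k-mers
    is ``coverage * (read_length - k + 1) / read_length``. Insert sizes are
    Gaussian with sd = 10% of the mean, a conventional figure for a
    Covaris-sheared short-insert library.
    """

    read_length: int = 150
    insert_size: int = 350
    insert_sd: float = 35.0
    coverage: float = 70.0
    error_rate: float = 0.003
    quality_high: int = 36
    quality_low: int = 2
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.insert_size < 2 * self.read_length and not self.allow_overlap:
            raise ValueError(
                "insert_size < 2*read_length requires allow_overlap=True"
            )


@dataclass
class SimulatedReads:
    """Paired read batches plus per-pair ground truth.

    ``haplotype``, ``start`` and ``insert`` give each fragment's source:
    read 1 is the forward strand of [start, start+read_length); read 2 is
    the reverse complement of [start+insert-read_length, start+insert).
    ``n_errors`` counts injected substitutions over both mates.
    """

    batch1: ReadBatch
    batch2: ReadBatch
    haplotype: np.ndarray  # uint8 per pair, 0=A 1=B
    start: np.ndarray  # int64 fragment start per pair
    insert: np.ndarray  # int64 fragment length per pair
    n_errors: int
    sim: ReadSimSpec

    @property
    def n_pairs(self) -> int:
        return int(self.haplotype.size)


def _codes_to_strings(mat: np.ndarray) -> list[str]:
    # one big ASCII buffer, then slice: much faster than per-row decode
    n, m = mat.shape
    buf = CODE_TO_BASE[mat].tobytes()
    return [buf[i * m : (i + 1) * m].decode("ascii") for i in range(n)]


def simulate_reads(genome: DiploidGenome, sim: ReadSimSpec) -> SimulatedReads:
    """Sample paired 2x``read_length`` reads from both haplotypes.

    Fragments are uniform over each haplotype; each sequenced base is
    substituted with probability ``error_rate`` (to a uniformly chosen
    different base) and assigned ``quality_low``, all other bases
    ``quality_high``.
    """
    L = genome.length
    rl = sim.read_length
    if L < max(rl, sim.insert_size):
        raise ValueError("genome shorter than a fragment")
    n_pairs = int(round(sim.coverage * L / (2 * rl)))
    if n_pairs < 1:
        raise ValueError("coverage too low: zero read pairs would be drawn")

    rng = np.random.default_rng(sim.seed)
    hap = (rng.random(n_pairs) < 0.5).astype(np.uint8)
    ins = np.rint(rng.normal(sim.insert_size, sim.insert_sd, n_pairs)).astype(np.int64)
    lo = rl if sim.allow_overlap else 2 * rl
    ins = np.clip(ins, lo, L)
    start = np.floor(rng.random(n_pairs) * (L - ins + 1)).astype(np.int64)

    haps = (genome.a_codes, genome.b_codes)
    offs = np.arange(rl, dtype=np.int64)
    qh = chr(PHRED_OFFSET + sim.quality_high)
    ql = chr(PHRED_OFFSET + sim.quality_low)

    seqs1: list[str] = []
    seqs2: list[str] = []
    quals1: list[str] = []
    quals2: list[str] = []
    n_errors = 0
    chunk = 100_000
    for c0 in range(0, n_pairs, chunk):
        c1 = min(c0 + chunk, n_pairs)
        h = hap[c0:c1]
        s = start[c0:c1]
        e = s + ins[c0:c1]
        idx1 = s[:, None] + offs
        idx2 = (e - rl)[:, None] + offs
        m1 = np.empty(idx1.shape, dtype=np.uint8)
        m2 = np.empty(idx2.shape, dtype=np.uint8)
        for hv in (0, 1):
            rows = h == hv
            m1[rows] = haps[hv][idx1[rows]]
            m2[rows] = haps[hv][idx2[rows]]
        # read 2 reports the reverse strand of the fragment's far end
        m2 = 3 - m2[:, ::-1]
        for mat, seq_out, qual_out in ((m1, seqs1, quals1), (m2, seqs2, quals2)):
            if sim.error_rate > 0:
                emask = rng.random(mat.shape) < sim.error_rate
                ne = int(np.count_nonzero(emask))
                n_errors += ne
                if ne:
                    mat[emask] = (mat[emask] + rng.integers(1, 4, ne).astype(np.uint8)) % 4
                # build quality strings from the error mask via one bytes buffer
                qbuf = np.where(emask, np.uint8(ord(ql)), np.uint8(ord(qh))).tobytes()
                m = mat.shape[1]
                qual_out.extend(
                    qbuf[i * m : (i + 1) * m].decode("ascii")
                    for i in range(mat.shape[0])
                )
            else:
                qual_out.extend([qh * rl] * mat.shape[0])
            seq_out.extend(_codes_to_strings(mat))

    ids1 = [f"sim_{i}/1" for i in range(n_pairs)]
    ids2 = [f"sim_{i}/2" for i in range(n_pairs)]
    return SimulatedReads(
        batch1=ReadBatch(ids1, seqs1, quals1),
        batch2=ReadBatch(ids2, seqs2, quals2),
        haplotype=hap,
        start=start,
        insert=ins,
        n_errors=n_errors,
        sim=sim,
    )


def fragment_assembly(
    genome: DiploidGenome,
    n_contigs: int,
    gap_length: int = 100,
    seed: int = 0,
    max_contigs_per_scaffold: int = 4,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Cut haplotype A into contigs and join runs of them into scaffolds.

    Contigs partition haplotype A exactly (their lengths sum to the haploid
    length). Consecutive contigs are grouped into scaffolds of 1 to
    ``max_contigs_per_scaffold`` members, joined by ``gap_length`` Ns.
    Returns (contigs, scaffolds) as lists of (id, sequence) pairs.
    """
    L = genome.length
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if n_contigs > L:
        raise ValueError("n_contigs exceeds genome length")
    rng = np.random.default_rng(seed)
    if n_contigs == 1:
        cuts = np.array([], dtype=np.int64)
    else:
        cuts = np.sort(rng.choice(np.arange(1, L), size=n_contigs - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [L]])
    seq_a = genome.haplotype_a
    contigs = [
        (f"contig_{i}", seq_a[int(bounds[i]) : int(bounds[i + 1])])
        for i in range(n_contigs)
    ]

    scaffolds: list[tuple[str, str]] = []
    i = 0
    s = 0
    gap = "N" * gap_length
    while i < n_contigs:
        run = int(rng.integers(1, max_contigs_per_scaffold + 1))
        members = contigs[i : i + run]
        scaffolds.append((f"scaffold_{s}", gap.join(seq for _n, seq in members)))
        i += run
        s += 1
    return contigs, scaffolds


def write_ground_truth(genome: DiploidGenome, out_dir: str | Path) -> None:
    """Write het positions (TSV), repeat intervals (TSV) and the spec (JSON)."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "het_positions.tsv", "w") as fh:
        fh.write("position\n")
        for p in genome.het_positions:
            fh.write(f"{int(p)}\n")
    with open(out / "repeat_intervals.tsv", "w") as fh:
        fh.write("start\tend\n")
        for a, b in genome.repeat_intervals:
            fh.write(f"{a}\t{b}\n")
    with open(out / "genome_spec.json", "w") as fh:
        json.dump(
            {
                "haploid_length": genome.spec.haploid_length,
                "gc_fraction": genome.spec.gc_fraction,
                "repeat_fraction": genome.spec.repeat_fraction,
                "repeat_unit_length": genome.spec.repeat_unit_length,
                "het_rate": genome.spec.het_rate,
                "seed": genome.spec.seed,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
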