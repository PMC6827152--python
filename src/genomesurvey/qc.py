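"""Paired-read filtering and sequencing quality statistics.

Filtering follows common survey-sequencing practice: a read PAIR is
discarded whole (never orphaned, which would bias downstream k-mer
coverage) if either mate

* contains any of the supplied adapter sequences as an exact substring,
* has a fraction of N bases above ``max_n_frac``, or
* has more than ``max_lowq_frac`` of its bases below Phred ``min_q``.

Surviving reads are untouched — no trimming. The summary statistics mirror
the conventional sequencing-report columns: raw/clean bases, effective
rate (clean/raw), mean per-base error rate implied by the Phred scores,
Q20, Q30 and GC content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ReadBatch

__all__ = ["QCStats", "FilterResult", "filter_reads", "compute_quality_stats", "run_qc"]


@dataclass
class QCStats:
    """Quality summary of a clean read set (percentages in 0-100)."""

    raw_bases: int
    clean_bases: int
    effective_rate: float  # 100 * clean_bases / raw_bases
    error_rate: float  # 100 * mean over bases of 10^(-Q/10)
    q20: float  # percent of bases with Phred >= 20
    q30: float  # percent of bases with Phred >= 30
    gc_content: float  # percent G+C among A/C/G/T bases

    def __post_init__(self) -> None:
        if self.clean_bases > self.raw_bases:
            raise ValueError("clean_bases cannot exceed raw_bases")

    def as_dict(self) -> dict:
        return {
            "raw_bases": self.raw_bases,
            "clean_bases": self.clean_bases,
            "effective_rate": self.effective_rate,
            "error_rate": self.error_rate,
            "q20": self.q20,
            "q30": self.q30,
            "gc_content": self.gc_content,
        }


@dataclass
class FilterResult:
    clean1: ReadBatch
    clean2: ReadBatch
    raw_bases: int
    clean_bases: int
    pairs_in: int
    pairs_kept: int
    dropped_adapter: int
    dropped_n: int
    dropped_quality: int

    @property
    def effective_rate(self) -> float:
        return 100.0 * self.clean_bases / self.raw_bases if self.raw_bases else 0.0


def _mate_fail(
    batch: ReadBatch,
    adapters: Sequence[str],
    max_n_frac: float,
    min_q: int,
    max_lowq_frac: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-read failure flags (adapter, N, low quality) for one batch."""
    n = len(batch)
    fail_ad = np.zeros(n, dtype=bool)
    fail_n = np.zeros(n, dtype=bool)
    for i, seq in enumerate(batch.seqs):
        if adapters and any(a in seq for a in adapters):
            fail_ad[i] = True
        ln = len(seq)
        if ln and seq.count("N") / ln > max_n_frac:
            fail_n[i] = True
    # low-quality fractions vectorised over the flattened quality array
    lengths = np.fromiter((len(s) for s in batch.seqs), dtype=np.int64, count=n)
    fail_q = np.zeros(n, dtype=bool)
    if n and lengths.sum() > 0:
        low = (batch.phred() < min_q).astype(np.int64)
        offsets = np.zeros(n, dtype=np.int64)
        np.cumsum(lengths[:-1], out=offsets[1:])
        nz = lengths > 0
        counts = np.zeros(n, dtype=np.int64)
        counts[nz] = np.add.reduceat(low, offsets[nz])
        fail_q[nz] = counts[nz] / lengths[nz] > max_lowq_frac
    return fail_ad, fail_n, fail_q


def filter_reads(
    raw1: ReadBatch,
    raw2: ReadBatch,
    adapter_seqs: Sequence[str] = (),
    max_n_frac: float = 0.1,
    min_q: int = 5,
    max_lowq_frac: float = 0.5,
) -> FilterResult:
    """Drop contaminated / low-quality pairs jointly; never trim.

    Drop reasons are attributed with precedence adapter > N > quality when
    a pair fails more than one rule.
    """
    if len(raw1) != len(raw2):
        raise ValueError("paired batches must have equal record counts")
    a1, n1, q1 = _mate_fail(raw1, adapter_seqs, max_n_frac, min_q, max_lowq_frac)
    a2, n2, q2 = _mate_fail(raw2, adapter_seqs, max_n_frac, min_q, max_lowq_frac)
    ad = a1 | a2
    nn = (n1 | n2) & ~ad
    qq = (q1 | q2) & ~ad & ~nn
    keep = ~(ad | nn | qq)
    clean1 = raw1.subset(keep)
    clean2 = raw2.subset(keep)
    raw_bases = raw1.n_bases + raw2.n_bases
    clean_bases = clean1.n_bases + clean2.n_bases
    return FilterResult(
        clean1=clean1,
        clean2=clean2,
        raw_bases=raw_bases,
        clean_bases=clean_bases,
        pairs_in=len(raw1),
        pairs_kept=len(clean1),
        dropped_adapter=int(ad.sum()),
        dropped_n=int(nn.sum()),
        dropped_quality=int(qq.sum()),
    )


def compute_quality_stats(
    clean1: ReadBatch,
    clean2: ReadBatch | None = None,
    raw_bases: int | None = None,
) -> QCStats:
    """Q20/Q30/error-rate/GC summary of a clean (pair of) batch(es).

    ``error_rate`` is the mean Phred-implied substitution probability,
    100 * mean(10^(-Q/10)); Q20/Q30 are the percent of bases at accuracy
    >= 99% / >= 99.9%. N bases are excluded from the GC denominator.
    """
    batches = [clean1] + ([clean2] if clean2 is not None else [])
    total = sum(len(b) for b in batches)
    if total == 0:
        raise ValueError("empty batch")
    phreds = np.concatenate([b.phred() for b in batches])
    nb = int(phreds.size)
    q20 = 100.0 * np.count_nonzero(phreds >= 20) / nb
    q30 = 100.0 * np.count_nonzero(phreds >= 30) / nb
    err = 100.0 * float(np.mean(10.0 ** (-phreds / 10.0)))
    gc = at = 0
    for b in batches:
        for s in b.seqs:
            gc += s.count("G") + s.count("C")
            at += s.count("A") + s.count("T")
    gc_content = 100.0 * gc / (gc + at) if gc + at else 0.0
    clean_bases = nb
    rb = raw_bases if raw_bases is not None else clean_bases
    return QCStats(
        raw_bases=rb,
        clean_bases=clean_bases,
        effective_rate=100.0 * clean_bases / rb if rb else 0.0,
        error_rate=err,
        q20=q20,
        q30=q30,
        gc_content=gc_content,
    )


def run_qc(
    raw1: ReadBatch,
    raw2: ReadBatch,
    adapter_seqs: Sequence[str] = (),
    max_n_frac: float = 0.1,
    min_q: int = 5,
    max_lowq_frac: float = 0.5,
) -> tuple[ReadBatch, ReadBatch, QCStats]:
    """Filter a pair of batches and compute the full quality summary."""
    res = filter_reads(raw1, raw2, adapter_seqs, max_n_frac, min_q, max_lowq_frac)
    stats = compute_quality_stats(res.clean1, res.clean2, raw_bases=res.raw_bases)
    return res.clean1, res.clean2, stats
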