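"""Perfect microsatellite (SSR) detection and class summaries.

A locus is reported for every maximal perfect tandem run of a primitive
unit of length 2-6 whose span of complete copies is at least
``min_total_len`` bases (default 12, i.e. minimum copy numbers 6/4/3/3/2
for di- through hexa-nucleotides). Mononucleotide runs are excluded;
imperfect or compound repeats are reported as their separate perfect runs.

Maximality is defined on the periodic region: a run cannot be extended by
even a single base that preserves the period on either side, and complete
copies are counted from the region's left end. Phase-shifted sub-runs of
the same region are therefore not reported, which guarantees that records
of the same unit length never overlap. Runs containing N are split at
the N.

Motifs are canonicalised to the lexicographically smallest rotation among
the unit and its reverse complement, so e.g. TG, GT, CA and AC loci all
summarise under motif AC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._encode import revcomp

__all__ = [
    "SSRRecord",
    "SSRSummary",
    "canonical_motif",
    "primitive_unit",
    "find_ssrs",
    "summarize_ssrs",
]

CLASS_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SSRRecord:
    sequence_id: str
    start: int  # 0-based half-open span of complete copies
    end: int
    motif: str  # canonical unit
    unit_length: int  # 2..6
    copies: int

    @property
    def span_length(self) -> int:
        return self.end - self.start

    @property
    def ssr_class(self) -> str:
        return CLASS_NAMES[self.unit_length]


def primitive_unit(unit: str) -> str:
    """Shortest unit whose repetition forms ``unit`` (the primitive root)."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return unit[:p]
    return unit


def canonical_motif(unit: str) -> str:
    """Smallest string among all rotations of the unit and of its revcomp.

    Units that are powers of a shorter unit are first reduced to their
    primitive root (e.g. ATAT -> AT), so the motif is always primitive.
    """
    if not 1 <= len(unit) <= 6:
        raise ValueError("unit length must be 1-6")
    if any(c not in "ACGT" for c in unit):
        raise ValueError("unit must be over A/C/G/T")
    unit = primitive_unit(unit)
    rc = revcomp(unit)
    n = len(unit)
    cands = {unit[i:] + unit[:i] for i in range(n)} | {rc[i:] + rc[:i] for i in range(n)}
    return min(cands)


def _scan_segment(
    seq: str, offset: int, seq_id: str, min_total_len: int
) -> list[SSRRecord]:
    """Scan one N-free segment for maximal period-m runs, m in 2..6."""
    n = len(seq)
    records: list[SSRRecord] = []
    if n < 4:
        return records
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for m in range(2, 7):
        if n < 2 * m:
            continue
        eq = arr[: n - m] == arr[m:]
        # boundaries of maximal True runs in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)  # exclusive
        for i, j in zip(run_starts, run_ends):
            region_len = int(j - i) + m  # period m holds over seq[i : j+m)
            copies = region_len // m
            if copies < 2:
                continue
            span = copies * m
            if span < min_total_len:
                continue
            unit = seq[i : i + m]
            if primitive_unit(unit) != unit:
                continue  # covered by the shorter period's scan
            records.append(
                SSRRecord(
                    sequence_id=seq_id,
                    start=offset + int(i),
                    end=offset + int(i) + span,
                    motif=canonical_motif(unit),
                    unit_length=m,
                    copies=copies,
                )
            )
    return records


def find_ssrs(
    sequence: str | tuple[str, str],
    min_total_len: int = 12,
    sequence_id: str = "seq",
) -> list[SSRRecord]:
    """All perfect SSR loci of a sequence, sorted by (start, unit_length).

    Accepts a plain sequence string or an (id, sequence) tuple. Regions
    containing N are split at the N and scanned separately.
    """
    if isinstance(sequence, tuple):
        sequence_id, seq = sequence
    else:
        seq = sequence
    seq = seq.upper()
    records: list[SSRRecord] = []
    pos = 0
    for segment in seq.split("N"):
        if len(segment) >= 4:
            records.extend(_scan_segment(segment, pos, sequence_id, min_total_len))
        pos += len(segment) + 1
    records.sort(key=lambda r: (r.start, r.unit_length))
    return records


@dataclass
class SSRSummary:
    """Class counts (di..hexa) with percentages of the total, 2 dp."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, float]

    def as_dict(self) -> dict:
        return {"counts": self.counts, "total": self.total, "percentages": self.percentages}


def summarize_ssrs(records: Iterable[SSRRecord] | Sequence[int]) -> SSRSummary:
    """Summarise records (or raw per-class counts di..hexa) into class shares.

    Accepts either a list of :class:`SSRRecord` or a 5-sequence of counts
    in class order (di, tri, tetra, penta, hexa). Percentages are rounded
    to 2 decimal places.
    """
    counts = {name: 0 for name in CLASS_NAMES.values()}
    recs = list(records)
    if recs and isinstance(recs[0], (int, np.integer)):
        if len(recs) != 5:
            raise ValueError("expected 5 class counts (di..hexa)")
        for name, c in zip(CLASS_NAMES.values(), recs):
            counts[name] = int(c)
    else:
        for r in recs:
            counts[r.ssr_class] += 1
    total = sum(counts.values())
    if total:
        percentages = {name: round(100.0 * c / total, 2) for name, c in counts.items()}
    else:
        percentages = {name: 0.0 for name in counts}
    return SSRSummary(counts=counts, total=total, percentages=percentages)


def write_records_tsv(records: Sequence[SSRRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tmotif\tclass\tcopies\n")
        for r in records:
            fh.write(
                f"{r.sequence_id}\t{r.start}\t{r.end}\t{r.motif}\t{r.ssr_class}\t{r.copies}\n"
            )


def write_records_gff3(records: Sequence[SSRRecord], path: str | Path) -> None:
    """GFF3 with one ``microsatellite`` feature per locus (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(records):
            attrs = f"ID=ssr{i};motif={r.motif};copies={r.copies};class={r.ssr_class}"
            fh.write(
                f"{r.sequence_id}\tgenomesurvey\tmicrosatellite\t{r.start + 1}\t{r.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )
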