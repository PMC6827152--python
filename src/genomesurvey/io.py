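"""Read batches and FASTQ/FASTA/histogram file I/O.

Parsing of the standard formats is delegated to Biopython's low-level
iterators (FastqGeneralIterator, SimpleFastaParser); this module only adds
the in-memory :class:`ReadBatch` container that flows through QC and k-mer
counting, and writers that keep outputs byte-deterministic.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


@dataclass
class ReadBatch:
    """A batch of reads: parallel lists of ids, sequences and quality strings.

    Qualities are stored as Phred+33 ASCII strings exactly as they appear in
    FASTQ; :meth:`phred` converts to a flat numeric array on demand. Two
    batches of equal length in the same order form a read pair.
    """

    ids: list[str] = field(default_factory=list)
    seqs: list[str] = field(default_factory=list)
    quals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.seqs) == len(self.quals)):
            raise ValueError("ids, seqs and quals must have equal lengths")
        for s, q in zip(self.seqs, self.quals):
            if len(s) != len(q):
                raise ValueError("sequence/quality length mismatch in record")

    def __len__(self) -> int:
        return len(self.seqs)

    @property
    def n_bases(self) -> int:
        return sum(len(s) for s in self.seqs)

    def phred(self) -> np.ndarray:
        """Flat array of Phred scores over every base in the batch."""
        joined = "".join(self.quals).encode("ascii")
        return np.frombuffer(joined, dtype=np.uint8).astype(np.int32) - PHRED_OFFSET

    def subset(self, keep: np.ndarray) -> "ReadBatch":
        idx = np.flatnonzero(np.asarray(keep))
        return ReadBatch(
            ids=[self.ids[i] for i in idx],
            seqs=[self.seqs[i] for i in idx],
            quals=[self.quals[i] for i in idx],
        )


def read_fastq(path: str | Path) -> ReadBatch:
    """Load a (optionally gzipped) FASTQ file into a :class:`ReadBatch`."""
    ids, seqs, quals = [], [], []
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            ids.append(title.split()[0])
            seqs.append(seq.upper())
            quals.append(qual)
    return ReadBatch(ids, seqs, quals)


def write_fastq(batch: ReadBatch, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in zip(batch.ids, batch.seqs, batch.quals):
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Load FASTA as a list of (id, sequence) tuples, uppercased."""
    with _open_text(path) as fh:
        return [(title.split()[0], seq.upper()) for title, seq in SimpleFastaParser(fh)]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq_seqs(path: str | Path) -> Iterator[str]:
    """Stream sequences only (for k-mer counting of large files)."""
    with _open_text(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq.upper()
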