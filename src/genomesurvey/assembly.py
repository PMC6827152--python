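"""Assembly summary statistics: total/max length, N50, N90.

N50/N90 follow the accumulation definition: sort sequences longest first,
add lengths until the running total reaches (>=) 50% / 90% of the grand
total; the length of the last sequence added is the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["AssemblyStats", "compute_stats", "stats_from_lengths"]


@dataclass
class AssemblyStats:
    total_length: int
    total_number: int
    max_length: int
    n50: int
    n90: int

    def __post_init__(self) -> None:
        if not (self.n90 <= self.n50 <= self.max_length <= self.total_length):
            raise ValueError("invariant n90 <= n50 <= max <= total violated")
        if self.total_number < 1:
            raise ValueError("at least one sequence required")

    def as_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "total_number": self.total_number,
            "max_length": self.max_length,
            "n50": self.n50,
            "n90": self.n90,
        }


def _nx(sorted_desc: np.ndarray, frac: float) -> int:
    total = int(sorted_desc.sum())
    cum = np.cumsum(sorted_desc)
    idx = int(np.searchsorted(cum, frac * total))  # first index with cum >= frac*total
    return int(sorted_desc[idx])


def stats_from_lengths(lengths: Iterable[int]) -> AssemblyStats:
    """Statistics from a bag of sequence lengths (zeros dropped with warning)."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    if (arr == 0).any():
        warnings.warn("skipping zero-length sequences", stacklevel=2)
        arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("no non-empty sequences")
    arr = np.sort(arr)[::-1]
    return AssemblyStats(
        total_length=int(arr.sum()),
        total_number=int(arr.size),
        max_length=int(arr[0]),
        n50=_nx(arr, 0.5),
        n90=_nx(arr, 0.9),
    )


def compute_stats(
    sequences: Sequence[tuple[str, str]] | Sequence[str],
    count_n_in_length: bool = True,
) -> AssemblyStats:
    """Assembly statistics for a FASTA record set.

    ``count_n_in_length=True`` (the convention for scaffolds) counts N gap
    characters toward sequence length; with False, only A/C/G/T count.
    """
    lengths = []
    for rec in sequences:
        seq = rec[1] if isinstance(rec, tuple) else rec
        if count_n_in_length:
            lengths.append(len(seq))
        else:
            lengths.append(len(seq) - seq.upper().count("N"))
    if not lengths:
        raise ValueError("empty sequence set")
    return stats_from_lengths(lengths)
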