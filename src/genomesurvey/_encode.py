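"""2-bit nucleotide encoding shared by the simulator and the k-mer counter.

A=0, C=1, G=2, T=3; every other byte (N, IUPAC ambiguity, separators)
maps to 4 and is treated as "not a base". Complement of code b is 3-b,
which is what makes the vectorised reverse-complement arithmetic work.
"""

from __future__ import annotations

import numpy as np

BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_LUT[ord(_b)] = _i
    BASE_LUT[ord(_b.lower())] = _i

CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes (4 for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return BASE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 renders as ``N``."""
    return CODE_TO_BASE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a string over A/C/G/T/N (case preserved)."""
    return seq.translate(_COMP)[::-1]
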