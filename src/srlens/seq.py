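"""Shared low-level sequence helpers: 2-bit encoding and reverse complement."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> 2-bit code; anything outside ACGT (upper) maps to 255
ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    ENCODE_TABLE[_b] = _c


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit codes (uint8) of a DNA string; non-ACGT become 255."""
    return ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_kmer(value: int, k: int) -> str:
    """Decode a 2-bit-packed k-mer integer back to a string."""
    bases = "ACGT"
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(bases[(value >> shift) & 3])
    return "".join(out)


def revcomp_kmer_values(values: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of 2-bit-packed k-mer integers."""
    values = np.asarray(values, dtype=np.int64)
    rc = np.zeros_like(values)
    v = values.copy()
    for _ in range(k):
        rc = (rc << 2) | ((~v) & 3)
        v >>= 2
    return rc
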