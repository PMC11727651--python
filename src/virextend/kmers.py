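"""2-bit k-mer encoding helpers (vectorized).

k-mers containing N are assigned code -1 and never participate in seeding
or matching.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, N=255)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Int64 codes of all k-mers of an encoded sequence; -1 where N occurs.

    k must satisfy 4**k < 2**63 (k <= 31).
    """
    n = len(enc)
    if n < k:
        return np.empty(0, dtype=np.int64)
    w = sliding_window_view(enc, k).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = (np.where(w == 255, 0, w) @ powers).astype(np.int64)
    codes[(w == 255).any(axis=1)] = -1
    return codes


def mismatches(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two equal-length encoded arrays (N mismatches everything)."""
    return int(np.count_nonzero(a != b))
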