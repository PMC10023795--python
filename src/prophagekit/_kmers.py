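"""Vectorized 2-bit k-mer encoding shared by the ANI sketcher and the
composition profiler.

A k-mer is encoded as an integer in base 4 (A=0, C=1, G=2, T=3), most
significant digit first; windows containing any ambiguity code are dropped.
For k <= 31 codes fit in int64.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

MAX_K = 31


def encode_kmers(sequence: str, k: int) -> np.ndarray:
    """Integer codes of all valid (ambiguity-free) k-mer windows, in order."""
    if k < 1 or k > MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} shorter than k={k}")
    base = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(base, k)
    valid = ~(windows < 0).any(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid] @ powers


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of the reverse complements of the given k-mer codes."""
    out = np.zeros_like(codes)
    rest = codes.copy()
    for _ in range(k):
        out = out * 4 + (3 - rest % 4)
        rest //= 4
    return out


def canonical_codes(sequence: str, k: int) -> np.ndarray:
    """Canonical (lexicographic min of strand and reverse complement) codes
    of all valid k-mer windows."""
    fwd = encode_kmers(sequence, k)
    return np.minimum(fwd, revcomp_codes(fwd, k))


def decode_kmer(code: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(bases))
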