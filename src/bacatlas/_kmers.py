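"""2-bit k-mer encoding utilities.

Sequences are encoded A=0, C=1, G=2, T=3; any other letter is invalid and no
k-mer spans it. A k-mer is packed into a uint64 (k <= 31). Canonical form is
the numeric minimum of a k-mer and its reverse complement, so hits are
orientation-free.
"""
from __future__ import annotations

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[ord(chr(_b).lower())] = _i

_EMPTY = np.empty(0, dtype=np.uint64)


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 code array (255 marks non-ACGT letters)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def kmer_codes(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """All valid k-mers of ``seq`` as packed uint64 codes, in positional order.

    Windows containing a non-ACGT letter are dropped. With ``canonical`` each
    code is min(forward, reverse-complement).
    """
    if not 0 < k <= 31:
        raise ValueError(f"k must be in 1..31, got {k}")
    codes = encode(seq)
    n = codes.size - k + 1
    if n <= 0:
        return _EMPTY
    valid = codes < 4
    # window is valid iff it contains no invalid letter
    bad = np.concatenate(([0], np.cumsum(~valid)))
    ok = (bad[k:] - bad[:-k]) == 0

    safe = np.where(valid, codes, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd |= safe[j : j + n] << np.uint64(2 * (k - 1 - j))
    if not canonical:
        return fwd[ok]

    comp = np.where(valid, 3 - codes, 0).astype(np.uint64)[::-1]
    rc_all = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        rc_all |= comp[j : j + n] << np.uint64(2 * (k - 1 - j))
    rc = rc_all[::-1]  # rc[i] is the reverse complement of window i
    return np.minimum(fwd, rc)[ok]


def kmer_positions(seq: str, k: int, canonical: bool = True):
    """(codes, positions) for all valid k-mer windows of ``seq``."""
    codes = encode(seq)
    n = codes.size - k + 1
    if n <= 0:
        return _EMPTY, np.empty(0, dtype=np.int64)
    valid = codes < 4
    bad = np.concatenate(([0], np.cumsum(~valid)))
    ok = (bad[k:] - bad[:-k]) == 0
    all_codes = kmer_codes(seq, k, canonical=canonical)
    return all_codes, np.flatnonzero(ok)


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN alphabet, case-insensitive, returns upper)."""
    table = str.maketrans("ACGTNacgtn", "TGCANTGCAN")
    return seq.translate(table)[::-1]
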