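"""Integer k-mer encoding shared by the mini classifier and composition vectors.

k-mers are packed 2 bits/base into uint64 (A=0, C=1, G=2, T=3), so k ≤ 31.
The canonical form of a k-mer is the lexicographic minimum of the k-mer and
its reverse complement, computed on the packed codes (packing preserves
lexicographic order).
"""

from __future__ import annotations

import numpy as np

_BASE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE[_b] = _i
    _BASE[_b + 32] = _i  # lowercase

_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 array with A,C,G,T -> 0..3 and anything else 255."""
    return _BASE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _CHARS[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    arr = encode(seq)
    out = np.where(arr > 3, np.uint8(255), 3 - arr)[::-1]
    chars = np.where(out > 3, np.uint8(ord("N")), _CHARS[np.minimum(out, 3)])
    return chars.tobytes().decode("ascii")


def _roll_codes(arr4: np.ndarray, k: int) -> np.ndarray:
    # arr4 must be in 0..3; rolling polynomial in base 4, window length k
    n = arr4.size - k + 1
    codes = np.zeros(n, dtype=np.uint64)
    a = arr4.astype(np.uint64)
    for i in range(k):
        codes = codes * np.uint64(4) + a[i : i + n]
    return codes


def canonical_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical packed codes for every k-window of an encoded sequence.

    Returns (codes, valid); windows containing a non-ACGT base are invalid
    (their code value is meaningless and must be masked by ``valid``).
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    bad = arr > 3
    clean = np.where(bad, np.uint8(0), arr)
    fwd = _roll_codes(clean, k)
    # window i's reverse complement is window (n-1-i) of the revcomp sequence
    rev = _roll_codes((3 - clean)[::-1], k)[::-1]
    canon = np.minimum(fwd, rev)
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        valid = (cs[k : k + n] - cs[:n]) == 0
    else:
        valid = np.ones(n, bool)
    return canon, valid


def rc_code(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse-complement of packed k-mer codes."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (np.uint64(3) - (c & np.uint64(3)))
        c >>= np.uint64(2)
    return out


def canonical_index(k: int) -> tuple[np.ndarray, int]:
    """Map every packed k-mer code (0..4^k-1) to a dense canonical feature index.

    Returns (lookup array of length 4^k, number of canonical k-mers).
    """
    codes = np.arange(4**k, dtype=np.uint64)
    canon = np.minimum(codes, rc_code(codes, k))
    uniq, inv = np.unique(canon, return_inverse=True)
    return inv.astype(np.int32), int(uniq.size)
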