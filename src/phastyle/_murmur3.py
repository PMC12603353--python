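"""MurmurHash3 x64-128, scalar and vectorized.

The sketcher hashes ASCII k-mers with MurmurHash3 and keeps the low 64 bits
(h1) of the 128-bit digest, interpreting byte blocks little-endian.  The
scalar implementation below follows the reference algorithm; the NumPy
version hashes a whole (n_kmers, kmer_len) byte matrix at once and is
cross-checked against the scalar path in the test suite.
"""

from __future__ import annotations

import numpy as np

_MASK = (1 << 64) - 1
_C1 = 0x87C37B91114253D5
_C2 = 0x4CF5AD432745937F


def _rotl(x: int, r: int) -> int:
    return ((x << r) | (x >> (64 - r))) & _MASK


def _fmix(k: int) -> int:
    k ^= k >> 33
    k = (k * 0xFF51AFD7ED558CCD) & _MASK
    k ^= k >> 33
    k = (k * 0xC4CEB9FE1A85EC53) & _MASK
    k ^= k >> 33
    return k


def murmur3_x64_128(data: bytes, seed: int = 0) -> tuple[int, int]:
    """Reference (pure-Python) MurmurHash3 x64-128 of ``data``."""
    length = len(data)
    h1 = h2 = seed & _MASK
    nblocks = length // 16
    for i in range(nblocks):
        k1 = int.from_bytes(data[16 * i : 16 * i + 8], "little")
        k2 = int.from_bytes(data[16 * i + 8 : 16 * i + 16], "little")
        k1 = (k1 * _C1) & _MASK
        k1 = _rotl(k1, 31)
        k1 = (k1 * _C2) & _MASK
        h1 ^= k1
        h1 = _rotl(h1, 27)
        h1 = (h1 + h2) & _MASK
        h1 = (h1 * 5 + 0x52DCE729) & _MASK
        k2 = (k2 * _C2) & _MASK
        k2 = _rotl(k2, 33)
        k2 = (k2 * _C1) & _MASK
        h2 ^= k2
        h2 = _rotl(h2, 31)
        h2 = (h2 + h1) & _MASK
        h2 = (h2 * 5 + 0x38495AB5) & _MASK
    tail = data[nblocks * 16 :]
    k1 = k2 = 0
    if len(tail) > 8:
        k2 = int.from_bytes(tail[8:], "little")
        k2 = (k2 * _C2) & _MASK
        k2 = _rotl(k2, 33)
        k2 = (k2 * _C1) & _MASK
        h2 ^= k2
    if tail:
        k1 = int.from_bytes(tail[:8], "little")
        k1 = (k1 * _C1) & _MASK
        k1 = _rotl(k1, 31)
        k1 = (k1 * _C2) & _MASK
        h1 ^= k1
    h1 ^= length
    h2 ^= length
    h1 = (h1 + h2) & _MASK
    h2 = (h2 + h1) & _MASK
    h1 = _fmix(h1)
    h2 = _fmix(h2)
    h1 = (h1 + h2) & _MASK
    h2 = (h2 + h1) & _MASK
    return h1, h2


def hash64(data: bytes, seed: int = 0) -> int:
    """Low 64 bits (h1) of the x64-128 digest."""
    return murmur3_x64_128(data, seed)[0]


def _rotl_np(x: np.ndarray, r: int) -> np.ndarray:
    return (x << np.uint64(r)) | (x >> np.uint64(64 - r))


def _fmix_np(k: np.ndarray) -> np.ndarray:
    k = k ^ (k >> np.uint64(33))
    k = k * np.uint64(0xFF51AFD7ED558CCD)
    k = k ^ (k >> np.uint64(33))
    k = k * np.uint64(0xC4CEB9FE1A85EC53)
    k = k ^ (k >> np.uint64(33))
    return k


def _le_uint64(blocks: np.ndarray) -> np.ndarray:
    """(n, m<=8) uint8 -> uint64 little-endian words, zero-padded."""
    n, m = blocks.shape
    out = np.zeros(n, dtype=np.uint64)
    for j in range(m):
        out |= blocks[:, j].astype(np.uint64) << np.uint64(8 * j)
    return out


def hash64_rows(rows: np.ndarray, seed: int = 0) -> np.ndarray:
    """Vectorized hash64 of every row of a (n, length) uint8 matrix."""
    rows = np.ascontiguousarray(rows, dtype=np.uint8)
    n, length = rows.shape
    c1 = np.uint64(_C1)
    c2 = np.uint64(_C2)
    h1 = np.full(n, np.uint64(seed & _MASK), dtype=np.uint64)
    h2 = h1.copy()
    nblocks = length // 16
    with np.errstate(over="ignore"):
        for i in range(nblocks):
            k1 = _le_uint64(rows[:, 16 * i : 16 * i + 8])
            k2 = _le_uint64(rows[:, 16 * i + 8 : 16 * i + 16])
            k1 = _rotl_np(k1 * c1, 31) * c2
            h1 ^= k1
            h1 = _rotl_np(h1, 27) + h2
            h1 = h1 * np.uint64(5) + np.uint64(0x52DCE729)
            k2 = _rotl_np(k2 * c2, 33) * c1
            h2 ^= k2
            h2 = _rotl_np(h2, 31) + h1
            h2 = h2 * np.uint64(5) + np.uint64(0x38495AB5)
        tail = rows[:, nblocks * 16 :]
        tail_len = tail.shape[1]
        if tail_len > 8:
            k2 = _le_uint64(tail[:, 8:])
            k2 = _rotl_np(k2 * c2, 33) * c1
            h2 ^= k2
        if tail_len:
            k1 = _le_uint64(tail[:, :8])
            k1 = _rotl_np(k1 * c1, 31) * c2
            h1 ^= k1
        h1 ^= np.uint64(length)
        h2 ^= np.uint64(length)
        h1 = h1 + h2
        h2 = h2 + h1
        h1 = _fmix_np(h1)
        h2 = _fmix_np(h2)
        h1 = h1 + h2
    return h1
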