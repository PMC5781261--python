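"""2-bit nucleotide encoding and vectorised kmer machinery.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, IUPAC codes,
padding) becomes the sentinel 4 and poisons every kmer window it touches.
A kmer of length k is packed into a uint64 with the first base in the most
significant 2-bit field, so lexicographic order of spellings equals numeric
order of codes. k must be odd and ≤ 31 so that no kmer equals its own
reverse complement and codes fit in 62 bits.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

SENTINEL = 4

_LUT = np.full(256, SENTINEL, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def encode_seq(seq: str) -> np.ndarray:
    """Encode one sequence string to a uint8 code array."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    """Decode a uint8 code array (no sentinels) back to a string."""
    return _DECODE[codes].tobytes().decode("ascii")


def encode_matrix(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into a sentinel-padded (n, max_len) uint8 matrix.

    Returns (matrix, lengths). Fixed-length inputs take a fast path that
    avoids per-row Python work.
    """
    n = len(seqs)
    if n == 0:
        return np.zeros((0, 0), dtype=np.uint8), np.zeros(0, dtype=np.int64)
    lengths = np.fromiter((len(s) for s in seqs), count=n, dtype=np.int64)
    width = int(lengths.max())
    if (lengths == width).all():
        flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        return _LUT[flat].reshape(n, width), lengths
    mat = np.full((n, width), SENTINEL, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : lengths[i]] = encode_seq(s)
    return mat, lengths


def revcomp_str(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def revcomp_codes(codes: np.ndarray | np.uint64, k: int) -> np.ndarray:
    """Vectorised reverse complement of packed kmer codes.

    Complements every base (XOR within the 2k-bit field), reverses the
    2-bit fields of the 64-bit word via the classic mask/byteswap trick,
    then right-aligns the result.
    """
    c = np.asarray(codes, dtype=np.uint64) ^ np.uint64((1 << (2 * k)) - 1)
    c = ((c & _M2) << np.uint64(2)) | ((c >> np.uint64(2)) & _M2)
    c = ((c & _M4) << np.uint64(4)) | ((c >> np.uint64(4)) & _M4)
    c = c.byteswap()
    return c >> np.uint64(64 - 2 * k)


def revcomp_code(code: int, k: int) -> int:
    """Scalar reverse complement of a packed kmer code (pure Python)."""
    c = code ^ ((1 << (2 * k)) - 1)
    out = 0
    for _ in range(k):
        out = (out << 2) | (c & 3)
        c >>= 2
    return out


def code_to_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode("ascii")


def kmer_to_code(kmer: str) -> int:
    code = 0
    for ch in kmer.upper():
        code = (code << 2) | int(_LUT[ord(ch)])
    return code


def canonical_kmer_matrix(
    mat: np.ndarray, lengths: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """All canonical kmer codes of every row of an encoded matrix.

    Returns (canon, valid): both (n, width-k+1). ``canon[i, j]`` is the
    canonical (min of forward and reverse-complement) code of the window
    starting at j; ``valid[i, j]`` is False when the window runs past the
    row's true length or contains a sentinel base.

    Rolling update: forward code shifts left and appends the new base;
    reverse-complement code shifts right and prepends the new base's
    complement at the top field.
    """
    n, width = mat.shape
    if width < k:
        return np.zeros((n, 0), dtype=np.uint64), np.zeros((n, 0), dtype=bool)
    m = width - k + 1
    b = mat.astype(np.uint64)
    bad = (mat >= SENTINEL).astype(np.int32)
    # windowed count of bad bases via cumulative sums
    cs = np.zeros((n, width + 1), dtype=np.int32)
    np.cumsum(bad, axis=1, out=cs[:, 1:])
    valid = (cs[:, k:] - cs[:, :-k]) == 0
    valid &= (np.arange(m)[None, :] + k) <= lengths[:, None]

    canon = np.empty((n, m), dtype=np.uint64)
    mask = np.uint64((1 << (2 * (k - 1))) - 1)
    top = np.uint64(2 * (k - 1))
    three = np.uint64(3)
    f = np.zeros(n, dtype=np.uint64)
    r = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        bi = b[:, i] & three
        f = (f << np.uint64(2)) | bi
        r = r | ((three - bi) << np.uint64(2 * i))
    np.minimum(f, r, out=canon[:, 0])
    for j in range(1, m):
        nb = b[:, j + k - 1] & three
        f = ((f & mask) << np.uint64(2)) | nb
        r = (r >> np.uint64(2)) | ((three - nb) << top)
        np.minimum(f, r, out=canon[:, j])
    return canon, valid


def forward_kmer_matrix(
    mat: np.ndarray, lengths: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand kmer codes of every row; same validity rules."""
    n, width = mat.shape
    if width < k:
        return np.zeros((n, 0), dtype=np.uint64), np.zeros((n, 0), dtype=bool)
    m = width - k + 1
    b = mat.astype(np.uint64)
    bad = (mat >= SENTINEL).astype(np.int32)
    cs = np.zeros((n, width + 1), dtype=np.int32)
    np.cumsum(bad, axis=1, out=cs[:, 1:])
    valid = (cs[:, k:] - cs[:, :-k]) == 0
    valid &= (np.arange(m)[None, :] + k) <= lengths[:, None]

    fwd = np.empty((n, m), dtype=np.uint64)
    mask = np.uint64((1 << (2 * (k - 1))) - 1)
    three = np.uint64(3)
    f = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        f = (f << np.uint64(2)) | (b[:, i] & three)
    fwd[:, 0] = f
    for j in range(1, m):
        f = ((f & mask) << np.uint64(2)) | (b[:, j + k - 1] & three)
        fwd[:, j] = f
    return fwd, valid


def revcomp_matrix(mat: np.ndarray, length: int | None = None) -> np.ndarray:
    """Reverse complement of a single encoded row (uint8 codes)."""
    arr = mat[::-1].copy()
    good = arr < SENTINEL
    arr[good] = 3 - arr[good]
    return arr


def iter_kmers(seq: str, k: int) -> Iterable[str]:
    """Canonical kmer strings of one sequence (test/debug convenience)."""
    mat, lengths = encode_matrix([seq])
    canon, valid = canonical_kmer_matrix(mat, lengths, k)
    for j in range(canon.shape[1]):
        if valid[0, j]:
            yield code_to_kmer(int(canon[0, j]), k)
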