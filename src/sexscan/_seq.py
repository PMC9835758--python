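"""Low-level sequence encoding and k-mer integer arithmetic (numpy, 2-bit codes)."""
from __future__ import annotations

import numpy as np

# A/C/G/T (either case) -> 0..3, anything else -> 255
CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    CODE[_b] = _i
    CODE[_b + 32] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """2-bit encode a sequence string (case-insensitive); non-ACGT -> 255."""
    return CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    if np.any(codes >= 4):
        raise ValueError("cannot decode invalid (non-ACGT) codes")
    return bytes(_DECODE[codes]).decode("ascii")


def mask_of(seq: str) -> np.ndarray:
    """Boolean array, True where the base is soft-masked (lowercase)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return (raw >= 97) & (raw <= 122)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis; invalid codes stay invalid."""
    rc = np.where(codes < 4, 3 - codes, codes)
    return rc[..., ::-1]


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


def kmer_ints_1d(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer integers at every position of a 1-D code array.

    Returns (ints, valid): ints[i] encodes codes[i:i+k]; valid[i] is False if
    the window contains a non-ACGT code. Both have length len(codes)-k+1.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    ints = np.zeros(n, np.uint64)
    c = codes.astype(np.uint64) & np.uint64(3)
    for j in range(k):
        ints = (ints << np.uint64(2)) | c[j : j + n]
    return ints, valid


def kmer_ints_2d(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer integers for every window of every row of (n, L) codes.

    Rows must be valid (codes < 4). Returns an (n, L-k+1) uint64 array.
    """
    n, L = codes.shape
    W = L - k + 1
    if W <= 0:
        return np.empty((n, 0), np.uint64)
    c = codes.astype(np.uint64)
    out = np.empty((n, W), np.uint64)
    v = np.zeros(n, np.uint64)
    for j in range(k):
        v = (v << np.uint64(2)) | c[:, j]
    out[:, 0] = v
    mask = np.uint64((1 << (2 * k)) - 1)
    for j in range(1, W):
        v = ((v << np.uint64(2)) & mask) | c[:, j + k - 1]
        out[:, j] = v
    return out


def canonical_ints_1d(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-collapsed) k-mer integers at every position of a sequence."""
    fwd, valid = kmer_ints_1d(codes, k)
    rc, _ = kmer_ints_1d(revcomp_codes(codes), k)
    return np.minimum(fwd, rc[::-1]), valid


def canonical_ints_2d(codes: np.ndarray, k: int) -> np.ndarray:
    fwd = kmer_ints_2d(codes, k)
    rc = kmer_ints_2d(revcomp_codes(codes), k)
    return np.minimum(fwd, rc[:, ::-1])


def int_to_kmer(value: int, k: int) -> str:
    out = bytearray(k)
    v = int(value)
    for j in range(k - 1, -1, -1):
        out[j] = b"ACGT"[v & 3]
        v >>= 2
    return out.decode("ascii")


def kmer_to_int(kmer: str) -> int:
    v = 0
    for c in encode(kmer):
        if c >= 4:
            raise ValueError(f"non-ACGT symbol in k-mer {kmer!r}")
        v = (v << 2) | int(c)
    return v


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer.upper() <= rc.upper() else rc
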