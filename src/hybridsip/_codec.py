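"""Nucleotide encoding and packed k-mer utilities.

Sequences are held either as Python strings over {A,C,G,T} or as uint8 code
arrays (A=0, C=1, G=2, T=3). k-mers are packed into uint64 words, two bits
per base, and reduced to canonical form (the lexicographically smaller of a
k-mer and its reverse complement) so that mapping is strand-agnostic.
k must satisfy k <= 31 so a packed k-mer fits a uint64.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array (A=0,C=1,G=2,T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def packed_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Forward-strand packed k-mers.

    codes: (n, L) or (L,) uint8 array; returns (n, L-k+1) or (L-k+1,) uint64.
    Rolling evaluation keeps memory at O(n) per window step.
    """
    if not 1 <= k <= 26:
        # 4^k and window sums must stay exactly representable in float64
        # for the 1-D matmul path; 26 gives 2*26=52 bits < 53
        raise ValueError("k must be in [1, 26]")
    if codes.ndim == 1:
        if len(codes) < k:
            raise ValueError(f"sequence length {len(codes)} shorter than k={k}")
        pow4 = (4.0 ** np.arange(k - 1, -1, -1)).astype(np.float64)
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        return (windows.astype(np.float64) @ pow4).astype(np.uint64)
    c = codes.astype(np.uint64)
    n, L = c.shape
    if L < k:
        raise ValueError(f"sequence length {L} shorter than k={k}")
    m = L - k + 1
    out = np.empty((n, m), dtype=np.uint64)
    four = np.uint64(4)
    v = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        v = v * four + c[:, j]
    out[:, 0] = v
    top = four ** np.uint64(k - 1)
    for i in range(1, m):
        v = (v - c[:, i - 1] * top) * four + c[:, i + k - 1]
        out[:, i] = v
    return out


_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def revcomp_packed(kmers: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mers by bit manipulation.

    Complement flips each 2-bit base (b -> b^3); reversal swaps 2-bit fields
    pairwise, then nibbles, then bytes, and shifts out the unused high bits.
    """
    x = kmers ^ np.uint64((1 << (2 * k)) - 1)
    x = ((x & _M2) << np.uint64(2)) | ((x >> np.uint64(2)) & _M2)
    x = ((x & _M4) << np.uint64(4)) | ((x >> np.uint64(4)) & _M4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def packed_kmers_rc(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed reverse-complement of each forward k-mer window."""
    return revcomp_packed(packed_kmers(codes, k), k)


def canonical_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (min of forward and reverse-complement) packed k-mers."""
    fwd = packed_kmers(codes, k)
    return np.minimum(fwd, revcomp_packed(fwd, k))
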