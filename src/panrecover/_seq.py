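"""Low-level sequence encoding helpers shared across the package.

Bases are encoded A=0, C=1, G=2, T=3 in ``uint8`` arrays; k-mers are packed
into ``uint64`` codes (2 bits per base), which limits k to 31. ``N`` and any
other character encode to 4 and poison every k-mer that covers them.
"""

from __future__ import annotations

import zlib

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array (A=0,C=1,G=2,T=3,other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[np.clip(codes, 0, 4)].tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of ``codes`` into a uint64, left-to-right.

    Positions whose window covers a non-ACGT base are set to the sentinel
    ``2**63`` (outside the 2k-bit code range) so they never match anything.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    c64 = codes.astype(np.uint64)
    for j in range(k):
        col = c64[j : j + n]
        out = (out << np.uint64(2)) | (col & np.uint64(3))
        bad |= codes[j : j + n] > 3
    out[bad] = np.uint64(1) << np.uint64(63)
    return out


def substream(seed: int, label: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def unique_kmer_index(codes: np.ndarray, k: int):
    """Positions of k-mers occurring exactly once, as (sorted codes, positions)."""
    kc = kmer_codes(codes, k)
    order = np.argsort(kc, kind="stable")
    sc = kc[order]
    if sc.size == 0:
        return sc, order
    # run-length over the sorted codes; singletons only
    new = np.empty(sc.size, dtype=bool)
    new[0] = True
    np.not_equal(sc[1:], sc[:-1], out=new[1:])
    starts = np.flatnonzero(new)
    counts = np.diff(np.append(starts, sc.size))
    single = starts[counts == 1]
    sc = sc[single]
    pos = order[single]
    keep = sc < (np.uint64(1) << np.uint64(63))
    return sc[keep], pos[keep]
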