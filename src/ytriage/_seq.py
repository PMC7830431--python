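"""Low-level nucleotide utilities shared across the package.

Sequences are plain Python strings over {A,C,G,T,N}; hot paths work on
numpy uint8 encodings (A=0, C=1, G=2, T=3, N=4).  N never matches any
base, including another N.
"""
from __future__ import annotations

import numpy as np

VALID_BASES = frozenset("ACGTN")
N_CODE = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
_ENCODE_LUT[ord("N")] = N_CODE

_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence to uint8 codes; raises on characters outside {A,C,G,T,N}."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc = _ENCODE_LUT[raw]
    if (enc == 255).any():
        bad = sorted({chr(c) for c in raw[enc == 255]})
        raise ValueError(f"non-IUPAC sequence characters: {bad}")
    return enc


def decode(enc: np.ndarray) -> str:
    return _DECODE_LUT[enc].tobytes().decode("ascii")


def match_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise base equality with N never matching."""
    return (a == b) & (a != N_CODE)


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit k-mer codes.

    Returns ``(codes, valid)`` of length ``len(enc) - k + 1``; ``valid`` is
    False for windows containing N.  Requires 2 <= k <= 31 (codes fit uint64).
    """
    if not 2 <= k <= 31:
        raise ValueError(f"k must be in [2, 31], got {k}")
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    clean = (enc != N_CODE).astype(np.int32)
    for j in range(k):
        codes = (codes << np.uint64(2)) | enc[j : j + n].astype(np.uint64)
    # window contains no N  <=>  sum of clean flags over the window == k
    csum = np.concatenate(([0], np.cumsum(clean)))
    valid = (csum[k:] - csum[:-k]) == k
    return codes, valid


def random_seq(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform A/C/G/T background sequence."""
    return decode(rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8))


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute an exact count round(divergence * len) of positions.

    Substitution-only divergence so planted coordinates stay exact; every
    substituted position receives a different base than the original.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    enc = encode(seq).copy()
    n_sub = int(round(divergence * len(seq)))
    if n_sub == 0:
        return seq
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    # shift by 1..3 mod 4 guarantees a different base; N positions left alone
    shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
    keep = enc[pos] != N_CODE
    enc[pos[keep]] = (enc[pos[keep]] + shift[keep]) % 4
    return decode(enc)
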