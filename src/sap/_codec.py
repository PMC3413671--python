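"""Byte-level nucleotide encoding shared by the index, mapper and simulator.

Bases are encoded as uint8 codes A=0, C=1, G=2, T=3, N=4.  Every character
outside {A,C,G,T} (including IUPAC ambiguity codes) collapses to N.  N never
seeds and never matches during scoring.
"""

from __future__ import annotations

import numpy as np

N_CODE = 4
_ALPHABET = "ACGTN"

_ENCODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE_LUT[ord(_c)] = _i
    _ENCODE_LUT[ord(_c.lower())] = _i

_DECODE_LUT = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-k window into a base-4 integer.

    Returns (values, valid) over all L-k+1 windows; ``valid`` is False for
    windows containing an N (their packed value is meaningless).  Requires
    k <= 31 so the packed value fits an int64.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for packed k-mer codes")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    is_base = codes < N_CODE
    vals = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        vals = vals * 4 + codes[j : j + n]
        valid &= is_base[j : j + n]
    return vals, valid


def pack_codes(codes: np.ndarray) -> int:
    """Pack a short code array (no Ns) into one base-4 integer."""
    v = 0
    for c in codes:
        v = v * 4 + int(c)
    return v
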