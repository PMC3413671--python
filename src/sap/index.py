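"""Hash index over all fixed-length substrings of the reference.

The index answers exact (FastMap) and one-mismatch (SlowMap) piece queries.
Both strands are searched: a query piece is looked up as-is and as its
reverse complement against the forward reference, which is equivalent to
additionally storing reverse-complement k-mers but halves the memory.

Internally each reference is held as a packed array of sorted k-mer codes
plus their start positions, so a lookup is two binary searches; repeated
k-mers share one run of the sorted array and memory stays linear in the
reference length.  The one-mismatch query uses the pigeonhole split: the
piece is cut into two halves, each half is looked up exactly, and the full
window is verified against the reference with at most one mismatch allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._codec import N_CODE, encode, kmer_codes, pack_codes, revcomp_codes
from .errors import ParameterError
from .io_formats import ReferenceSeq

__all__ = ["KmerIndex", "build_index", "lookup_exact", "lookup_one_mismatch",
           "save_index", "load_index"]

_INDEX_FORMAT_VERSION = 1

MIN_K = 8  # shorter seeds are too unspecific to anchor an alignment


@dataclass
class _SortedKmers:
    """Sorted packed k-mer codes with their 0-based start positions."""

    codes: np.ndarray
    positions: np.ndarray

    @classmethod
    def build(cls, ref_codes: np.ndarray, k: int) -> "_SortedKmers":
        vals, valid = kmer_codes(ref_codes, k)
        pos = np.flatnonzero(valid).astype(np.int64)
        vals = vals[valid]
        order = np.argsort(vals, kind="stable")  # stable keeps positions sorted per code
        return cls(vals[order], pos[order])

    def find(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.positions[lo:hi]


@dataclass
class _RefIndex:
    name: str
    codes: np.ndarray  # encoded reference sequence
    full: _SortedKmers
    half_a: _SortedKmers  # k-mers of length k//2 (pigeonhole left half)
    half_b: _SortedKmers  # k-mers of length k - k//2 (right half)


@dataclass
class KmerIndex:
    """Index of every k-length window of the references, N windows skipped."""

    k: int
    refs: list[_RefIndex] = field(default_factory=list)

    @property
    def ref_names(self) -> list[str]:
        return [r.name for r in self.refs]

    def n_positions(self, ref_id: int = 0) -> int:
        return len(self.refs[ref_id].full.positions)


def build_index(refs: Sequence[ReferenceSeq], k: int = 15) -> KmerIndex:
    """Index all k-length windows of ``refs``; windows containing N skipped."""
    if k < MIN_K:
        raise ParameterError(f"k={k} below minimum seed length {MIN_K}")
    idx = KmerIndex(k=k)
    ka = k // 2
    for ref in refs:
        codes = encode(ref.sequence)
        idx.refs.append(
            _RefIndex(
                name=ref.name,
                codes=codes,
                full=_SortedKmers.build(codes, k),
                half_a=_SortedKmers.build(codes, ka),
                half_b=_SortedKmers.build(codes, k - ka),
            )
        )
    return idx


def _fwd_exact(ref: _RefIndex, piece_codes: np.ndarray) -> np.ndarray:
    return ref.full.find(pack_codes(piece_codes))


def _fwd_one_mismatch(ref: _RefIndex, piece_codes: np.ndarray, k: int) -> np.ndarray:
    """Forward-strand window starts with Hamming distance <= 1 from the piece."""
    ka = k // 2
    cand = [ref.half_a.find(pack_codes(piece_codes[:ka]))]
    right = ref.half_b.find(pack_codes(piece_codes[ka:])) - ka
    cand.append(right[right >= 0])
    starts = np.unique(np.concatenate(cand))
    starts = starts[starts <= len(ref.codes) - k]
    if len(starts) == 0:
        return starts
    windows = ref.codes[starts[:, None] + np.arange(k)]
    mism = (windows != piece_codes).sum(axis=1)
    return starts[mism <= 1]


def _lookup(index: KmerIndex, piece: str, fn) -> list[tuple[int, str, int]]:
    codes = encode(piece)
    if len(codes) != index.k:
        raise ParameterError(f"piece length {len(codes)} != k={index.k}")
    if (codes == N_CODE).any():
        return []  # N never seeds
    rc = revcomp_codes(codes)
    hits: list[tuple[int, str, int]] = []
    for ref_id, ref in enumerate(index.refs):
        for strand, pc in (("+", codes), ("-", rc)):
            for p in fn(ref, pc):
                hits.append((ref_id, strand, int(p)))
    return hits


def save_index(index: KmerIndex, path) -> None:
    """Serialize an index to a single .npz archive (versioned header)."""
    payload = {
        "version": np.array([_INDEX_FORMAT_VERSION]),
        "k": np.array([index.k]),
        "names": np.array([r.name for r in index.refs]),
    }
    for i, r in enumerate(index.refs):
        payload[f"codes_{i}"] = r.codes
    with open(path, "wb") as fh:  # keep the exact filename (no .npz suffix)
        np.savez_compressed(fh, **payload)


def load_index(path) -> tuple[KmerIndex, list[ReferenceSeq]]:
    """Load a serialized index; returns (index, references)."""
    from ._codec import decode

    with np.load(path, allow_pickle=False) as data:
        version = int(data["version"][0])
        if version != _INDEX_FORMAT_VERSION:
            raise ParameterError(f"unsupported index format version {version}")
        k = int(data["k"][0])
        names = [str(n) for n in data["names"]]
        refs = [ReferenceSeq(name, decode(data[f"codes_{i}"])) for i, name in enumerate(names)]
    return build_index(refs, k=k), refs


def lookup_exact(index: KmerIndex, piece: str) -> list[tuple[int, str, int]]:
    """All exact occurrences of ``piece`` on either strand, as (ref, strand, pos)."""
    return _lookup(index, piece, lambda ref, pc: _fwd_exact(ref, pc))


def lookup_one_mismatch(index: KmerIndex, piece: str) -> list[tuple[int, str, int]]:
    """All window starts where the reference differs from ``piece`` in <= 1 base."""
    return _lookup(index, piece, lambda ref, pc: _fwd_one_mismatch(ref, pc, index.k))
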