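"""Seed-and-extend read mapping.

Each read is cut into a fixed number of pieces (default 7 x 15 bp) that are
looked up in the k-mer index, exactly (FastMap) or with up to one mismatch
(SlowMap).  Each hit implies a read start on the reference, l_i = MP_i - s_i;
hits on the same reference/strand whose implied starts agree within a small
window are clustered into candidate loci, and loci supported by at least two
pieces are extended: a gapless direct comparison when the cluster is
colinear (l_min == l_max), the band-restricted Smith-Waterman otherwise.
An alignment is kept only when its identity fraction S_map = L_map / n
exceeds 0.9 (strict), and the best accepted candidate by quality-weighted
final score is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._codec import N_CODE, encode, revcomp_codes
from .align import banded_align
from .errors import ParameterError
from .index import KmerIndex, _fwd_exact, _fwd_one_mismatch
from .io_formats import Read

__all__ = [
    "MapParams",
    "Piece",
    "CandidateLocus",
    "Alignment",
    "extract_pieces",
    "piece_starts",
    "seed_candidates",
    "direct_compare",
    "banded_sw",
    "accept_alignment",
    "final_score",
    "map_read",
    "map_reads",
]


@dataclass(frozen=True)
class MapParams:
    """Tunable mapping parameters (CLI-overridable)."""

    n_pieces: int = 7
    cluster_window: int = 30  # bp; InDels wider than this split into two loci
    band_margin: int = 5  # extra diagonals beyond the seed-implied offset range
    min_identity: float = 0.9  # the strict S_map acceptance threshold
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    max_candidates: int = 8  # loci tried per read, in rank order
    max_hits_per_piece: int = 100  # pieces hitting more loci are uninformative
    mapq: int = 60


@dataclass(frozen=True)
class Piece:
    index: int  # 1-based piece number
    start: int  # 0-based offset within the (oriented) read
    bases: str


@dataclass
class CandidateLocus:
    ref_id: int
    strand: str
    l_min: int
    l_max: int
    support: int  # number of distinct pieces in the cluster

    @property
    def width(self) -> int:
        return self.l_max - self.l_min


@dataclass
class Alignment:
    """A read-to-reference placement with edit operations and scores.

    ``bases``/``quals`` are in the orientation of the alignment (reverse
    complemented for '-' strand hits), matching the SAM convention.
    """

    read_id: str
    ref_name: str | None
    strand: str
    ref_start: int
    cigar: list[tuple[str, int]]
    bases: str
    quals: np.ndarray
    l_map: int = 0
    s_map: float = 0.0
    final_score: float = 0.0
    mapped: bool = False
    mapq: int = 0
    match_mask: np.ndarray | None = None
    dp_cells: int = 0

    @property
    def n(self) -> int:
        return len(self.bases)


def piece_starts(n: int, k: int, m: int = 7) -> list[int]:
    """Piece offsets s_i = round((i-1)(n-k)/(m-1)); first 0, last n-k."""
    if m < 2:
        raise ParameterError("need at least two pieces")
    span = n - k
    return [int((i * span) / (m - 1) + 0.5) for i in range(m)]


def extract_pieces(read: Read, k: int, m: int = 7) -> list[Piece]:
    n = len(read)
    if n < k:
        return []  # caller reports the read unmapped ("too short")
    return [Piece(i + 1, s, read.bases[s : s + k]) for i, s in enumerate(piece_starts(n, k, m))]


def _cluster_hits(
    hits_by_locus: dict[tuple[int, str], list[tuple[int, int]]], cluster_window: int
) -> list[CandidateLocus]:
    loci: list[CandidateLocus] = []
    for (ref_id, strand), hits in hits_by_locus.items():
        hits.sort()
        run: list[tuple[int, int]] = []
        for h in hits:
            if run and h[0] - run[-1][0] > cluster_window:
                loci.append(_make_locus(ref_id, strand, run))
                run = []
            run.append(h)
        if run:
            loci.append(_make_locus(ref_id, strand, run))
    loci = [c for c in loci if c.support >= 2]
    loci.sort(key=lambda c: (-c.support, c.width, c.ref_id, c.l_min, c.strand != "+"))
    return loci


def _make_locus(ref_id: int, strand: str, run: list[tuple[int, int]]) -> CandidateLocus:
    return CandidateLocus(
        ref_id=ref_id,
        strand=strand,
        l_min=run[0][0],
        l_max=run[-1][0],
        support=len({p for _, p in run}),
    )


def seed_candidates(
    read: Read,
    index: KmerIndex,
    mode: str = "fast",
    cluster_window: int = 30,
    n_pieces: int = 7,
    max_hits_per_piece: int = 100,
) -> list[CandidateLocus]:
    """Candidate loci from piece hits, ranked by support then compactness.

    Both read orientations are seeded; a '-' locus refers to the reverse
    complement of the read placed on the forward reference.
    """
    k = index.k
    n = len(read)
    if n < k:
        return []
    lookup = _fwd_exact if mode == "fast" else _fwd_one_mismatch
    fwd = encode(read.bases)
    starts = piece_starts(n, k, n_pieces)
    hits_by_locus: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for strand, codes in (("+", fwd), ("-", revcomp_codes(fwd))):
        for pi, s in enumerate(starts):
            pc = codes[s : s + k]
            if (pc == N_CODE).any():
                continue
            for ref_id, ref in enumerate(index.refs):
                if mode == "fast":
                    positions = lookup(ref, pc)
                else:
                    positions = lookup(ref, pc, k)
                if len(positions) > max_hits_per_piece:
                    continue
                for p in positions:
                    l = int(p) - s
                    if l < -(k - 1):
                        continue
                    hits_by_locus.setdefault((ref_id, strand), []).append((l, pi))
    return _cluster_hits(hits_by_locus, cluster_window)


def _oriented(read: Read, strand: str) -> tuple[str, np.ndarray, np.ndarray]:
    if strand == "+":
        return read.bases, read.quals, encode(read.bases)
    codes = revcomp_codes(encode(read.bases))
    from ._codec import decode

    return decode(codes), read.quals[::-1], codes


def direct_compare(
    read: Read, index: KmerIndex, locus: CandidateLocus, params: MapParams = MapParams()
) -> Alignment:
    """Gapless column-by-column comparison at the cluster's implied start.

    Bases falling beyond either reference end count as mismatches (emitted
    as insertions so the CIGAR stays within the reference).
    """
    bases, quals, codes = _oriented(read, locus.strand)
    ref = index.refs[locus.ref_id]
    n = len(codes)
    L = len(ref.codes)
    start = locus.l_min
    over_left = max(0, -start)
    over_right = max(0, start + n - L)
    mid = n - over_left - over_right
    match_mask = np.zeros(n, dtype=bool)
    if mid > 0:
        w = ref.codes[start + over_left : start + over_left + mid]
        r = codes[over_left : over_left + mid]
        match_mask[over_left : over_left + mid] = (r == w) & (r != N_CODE)
    cigar: list[tuple[str, int]] = []
    if over_left:
        cigar.append(("I", over_left))
    if mid > 0:
        cigar.append(("M", mid))
    if over_right:
        cigar.append(("I", over_right))
    l_map = int(match_mask.sum())
    return Alignment(
        read_id=read.id,
        ref_name=ref.name,
        strand=locus.strand,
        ref_start=max(0, start),
        cigar=cigar,
        bases=bases,
        quals=quals,
        l_map=l_map,
        s_map=l_map / n,
        mapped=False,
        mapq=params.mapq,
        match_mask=match_mask,
    )


def banded_sw(
    read: Read, index: KmerIndex, locus: CandidateLocus, params: MapParams = MapParams()
) -> Alignment | None:
    """Band-restricted Smith-Waterman extension over the cluster's diagonals."""
    bases, quals, codes = _oriented(read, locus.strand)
    ref = index.refs[locus.ref_id]
    res = banded_align(
        codes,
        ref.codes,
        locus.l_min - params.band_margin,
        locus.l_max + params.band_margin,
        match=params.match,
        mismatch=params.mismatch,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
    )
    if res is None:
        return None
    n = len(codes)
    return Alignment(
        read_id=read.id,
        ref_name=ref.name,
        strand=locus.strand,
        ref_start=res.ref_start,
        cigar=res.ops,
        bases=bases,
        quals=quals,
        l_map=res.l_map,
        s_map=res.l_map / n,
        mapped=False,
        mapq=params.mapq,
        match_mask=res.match_mask,
        dp_cells=res.cells,
    )


def accept_alignment(a: Alignment, min_identity: float = 0.9) -> bool:
    """Keep an alignment only when S_map is strictly greater than 0.9."""
    return a.s_map > min_identity


def final_score(a: Alignment, read: Read | None = None) -> float:
    """Quality-weighted identity in [0, 1].

    Sum of (1 - P_s(q)) over matching read positions divided by the sum over
    all read positions; reduces to S_map when all qualities are equal.
    """
    from .predictor import error_prob

    w = 1.0 - error_prob(a.quals)
    total = float(w.sum())
    if total <= 0.0:
        return 0.0
    if a.match_mask is None:
        return a.s_map
    return float(w[a.match_mask].sum()) / total


def _unmapped(read: Read) -> Alignment:
    return Alignment(
        read_id=read.id,
        ref_name=None,
        strand="+",
        ref_start=-1,
        cigar=[],
        bases=read.bases,
        quals=read.quals,
        mapped=False,
    )


def _tail_mismatches(a: Alignment, w: int = 15) -> int:
    """Largest number of mismatching positions in either terminal w bp."""
    mm = ~a.match_mask
    return int(max(mm[:w].sum(), mm[-w:].sum()))


def _try_candidates(
    read: Read, index: KmerIndex, loci: Sequence[CandidateLocus], params: MapParams
) -> Alignment | None:
    best: Alignment | None = None
    for locus in loci[: params.max_candidates]:
        if locus.width == 0:
            a = direct_compare(read, index, locus, params)
            # mismatches piled at an unanchored read end betray an InDel the
            # colinear seeds did not see; re-extend with the banded DP
            if not accept_alignment(a, params.min_identity) or _tail_mismatches(a) >= 3:
                b = banded_sw(read, index, locus, params)
                if b is not None and b.s_map > a.s_map:
                    a = b
        else:
            a = banded_sw(read, index, locus, params)
            if a is None:
                continue  # band excluded every full path; fall back to next locus
        if not accept_alignment(a, params.min_identity):
            continue
        a.final_score = final_score(a)
        a.mapped = True
        if best is None or a.final_score > best.final_score:
            best = a
        if best.final_score >= 1.0:
            break
    return best


def map_read(
    read: Read, index: KmerIndex, mode: str = "fast", params: MapParams = MapParams()
) -> Alignment:
    """Map one read; SlowMap retries one-mismatch seeding when exact fails."""
    if len(read) < index.k:
        return _unmapped(read)  # too short to seed
    loci = seed_candidates(
        read, index, "fast", params.cluster_window, params.n_pieces, params.max_hits_per_piece
    )
    best = _try_candidates(read, index, loci, params)
    if best is None and mode == "slow":
        loci = seed_candidates(
            read, index, "slow", params.cluster_window, params.n_pieces, params.max_hits_per_piece
        )
        best = _try_candidates(read, index, loci, params)
    return best if best is not None else _unmapped(read)


def map_reads(
    reads: Iterable[Read], index: KmerIndex, mode: str = "fast", params: MapParams = MapParams()
) -> list[Alignment]:
    return [map_read(r, index, mode, params) for r in reads]
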