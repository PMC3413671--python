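"""Band-restricted Smith-Waterman dynamic programming with affine gaps.

The alignment is read-global and reference-local ("glocal"): the whole read
must be consumed, while the alignment may start and end anywhere on the
reference.  The seed-implied offsets restrict the computed cells to the
diagonals ``diag_lo <= j - i <= diag_hi`` (i = read row, j = reference
column), so the work is O(n * band_width) instead of O(n * m).

Gap scoring: a gap of length g scores ``gap_open + (g - 1) * gap_extend``.
An N never matches (scored as a mismatch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._codec import N_CODE

NEG_INF = -(10**9)


@dataclass
class BandedResult:
    ref_start: int  # 0-based position of the first consumed reference base
    ops: list[tuple[str, int]]  # CIGAR-style (op, length), ops in M/I/D
    score: int
    l_map: int  # number of identically aligned bases
    match_mask: np.ndarray  # per-read-position: aligned and identical
    cells: int  # DP cells actually computed (O(n) bound check)


def banded_align(
    read_codes: np.ndarray,
    ref_codes: np.ndarray,
    diag_lo: int,
    diag_hi: int,
    *,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_extend: int = -1,
) -> BandedResult | None:
    """Align ``read_codes`` to ``ref_codes`` within the diagonal band.

    Returns None when the band admits no path that consumes the whole read.
    """
    n = len(read_codes)
    L = len(ref_codes)
    if n == 0:
        return None
    B = diag_hi - diag_lo + 1
    if B <= 0:
        return None

    read = read_codes.tolist()
    ref = ref_codes.tolist()

    # band-local storage: cell (i, b) is DP cell (i, j) with j = i + diag_lo + b
    H = [[NEG_INF] * B for _ in range(n + 1)]
    E = [[NEG_INF] * B for _ in range(n + 1)]  # gap in reference (read consumed, 'I')
    F = [[NEG_INF] * B for _ in range(n + 1)]  # gap in read (reference consumed, 'D')
    ptrH = [[0] * B for _ in range(n + 1)]  # 1=diag, 2=from E, 3=from F
    ptrE = [[0] * B for _ in range(n + 1)]  # 0=open from H, 1=extend
    ptrF = [[0] * B for _ in range(n + 1)]

    for b in range(B):
        j = diag_lo + b
        if 0 <= j <= L:
            H[0][b] = 0  # free reference prefix: alignment may start at any j

    cells = 0
    for i in range(1, n + 1):
        Hi, Ei, Fi = H[i], E[i], F[i]
        Hp, Ep = H[i - 1], E[i - 1]
        pHi, pEi, pFi = ptrH[i], ptrE[i], ptrF[i]
        rbase = read[i - 1]
        base_j = i + diag_lo
        for b in range(B):
            j = base_j + b
            if j < 0 or j > L:
                continue
            cells += 1
            best = NEG_INF
            ptr = 0
            # diagonal: consume read[i-1] and ref[j-1]
            if j >= 1:
                hd = Hp[b]
                if hd > NEG_INF:
                    cbase = ref[j - 1]
                    s = match if (rbase == cbase and rbase != N_CODE) else mismatch
                    cand = hd + s
                    if cand > best:
                        best, ptr = cand, 1
            # vertical: consume read base only (insertion relative to reference)
            if b + 1 < B:
                ho = Hp[b + 1]
                ee = Ep[b + 1]
                e_open = ho + gap_open if ho > NEG_INF else NEG_INF
                e_ext = ee + gap_extend if ee > NEG_INF else NEG_INF
                if e_open >= e_ext:
                    Ei[b], pEi[b] = e_open, 0
                else:
                    Ei[b], pEi[b] = e_ext, 1
                if Ei[b] > best:
                    best, ptr = Ei[b], 2
            # horizontal: consume reference base only (deletion from the read)
            if b >= 1 and j >= 1:
                ho = Hi[b - 1]
                ff = Fi[b - 1]
                f_open = ho + gap_open if ho > NEG_INF else NEG_INF
                f_ext = ff + gap_extend if ff > NEG_INF else NEG_INF
                if f_open >= f_ext:
                    Fi[b], pFi[b] = f_open, 0
                else:
                    Fi[b], pFi[b] = f_ext, 1
                if Fi[b] > best:
                    best, ptr = Fi[b], 3
            Hi[b] = best
            pHi[b] = ptr

    # free reference suffix: best score anywhere on the last row
    last = H[n]
    b_best, score = -1, NEG_INF
    for b in range(B):
        if last[b] > score:
            score, b_best = last[b], b
    if b_best < 0 or score <= NEG_INF:
        return None

    # traceback
    ops_rev: list[str] = []
    match_mask = np.zeros(n, dtype=bool)
    i, b = n, b_best
    state = "H"
    while i > 0:
        if state == "H":
            p = ptrH[i][b]
            if p == 1:
                j = i + diag_lo + b
                ops_rev.append("M")
                if read[i - 1] == ref[j - 1] and read[i - 1] != N_CODE:
                    match_mask[i - 1] = True
                i -= 1
            elif p == 2:
                state = "E"
            elif p == 3:
                state = "F"
            else:  # unreachable on a valid path
                return None
        elif state == "E":
            ops_rev.append("I")
            p = ptrE[i][b]
            i -= 1
            b += 1
            state = "E" if p == 1 else "H"
        else:  # state == "F"
            ops_rev.append("D")
            p = ptrF[i][b]
            b -= 1
            state = "F" if p == 1 else "H"
    ref_start = i + diag_lo + b  # i == 0 here

    ops: list[tuple[str, int]] = []
    for op in reversed(ops_rev):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    return BandedResult(
        ref_start=ref_start,
        ops=ops,
        score=score,
        l_map=int(match_mask.sum()),
        match_mask=match_mask,
        cells=cells,
    )
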