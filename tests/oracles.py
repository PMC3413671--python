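"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method available
(full dynamic programming, sliding-window scans, direct probability
arithmetic) and share no code with the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np

NEG = -(10**9)


def full_sw_glocal(
    read: np.ndarray,
    ref: np.ndarray,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_extend: int = -1,
) -> int:
    """Unrestricted read-global/reference-local affine alignment score.

    Full O(n*m) matrices; gap of length g scores gap_open+(g-1)*gap_extend.
    N (code 4) never matches.
    """
    n, m = len(read), len(ref)
    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    H[0, :] = 0
    for i in range(1, n + 1):
        for j in range(0, m + 1):
            e = max(H[i - 1, j] + gap_open, E[i - 1, j] + gap_extend)
            E[i, j] = e
            best = e
            if j >= 1:
                s = match if (read[i - 1] == ref[j - 1] and read[i - 1] != 4) else mismatch
                best = max(best, H[i - 1, j - 1] + s)
                f = max(H[i, j - 1] + gap_open, F[i, j - 1] + gap_extend)
                F[i, j] = f
                best = max(best, f)
            H[i, j] = best
    return int(H[n, :].max())


def hamming_occurrences(ref: str, piece: str, max_mismatch: int) -> list[int]:
    """Start positions where ref window differs from piece in <= max_mismatch
    bases (N counts as a mismatch)."""
    k = len(piece)
    out = []
    for p in range(len(ref) - k + 1):
        window = ref[p : p + k]
        d = sum(1 for a, b in zip(window, piece) if a != b or a == "N" or b == "N")
        if d <= max_mismatch:
            out.append(p)
    return out


def brute_posteriors(
    bases: str, quals: list[int], ref_base: str, r: float = 0.001
) -> tuple[str, str, np.ndarray]:
    """Direct evaluation of the three genotype posteriors at one site.

    Returns (b, b2, posteriors over [<b,b>, <b,b'>, <b',b'>]).  Evaluates the
    likelihood terms read by read in plain floating point (adequate for the
    small columns used in tests).
    """
    order = "ACGT"
    counts = {c: bases.count(c) for c in order}
    # most frequent; ties prefer the reference base, then alphabetical
    rank = sorted(order, key=lambda c: (-counts[c], c != ref_base, c))
    b, b2 = rank[0], rank[1]
    if counts[b2] == 0:
        b2 = ref_base if ref_base != b else next(c for c in order if c != b)
    ps = [min(10.0 ** (-q / 10.0), 0.75) for q in quals]
    sel = [(x, p) for x, p in zip(bases, ps) if x in (b, b2)]
    n = len(sel)
    k = sum(1 for x, _ in sel if x == b)

    def hom(allele: str) -> float:
        v = 1.0
        for x, p in sel:
            v *= (1.0 - p) if x == allele else p / 3.0
        return v

    het = math.comb(n, k) * 0.5**n
    if b == ref_base:
        priors = (1.0 - r - r * r, r, r * r)
    elif b2 == ref_base:
        priors = (r * r, r, 1.0 - r - r * r)
    else:
        priors = (r * r, r, r * r)
    terms = np.array([hom(b) * priors[0], het * priors[1], hom(b2) * priors[2]])
    return b, b2, terms / terms.sum()
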