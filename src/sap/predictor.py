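"""Bayesian SNP calling and quality-sum InDel calling from accepted alignments.

At every covered reference site the two most frequent observed bases b and
b' define three candidate genotypes {<b,b>, <b,b'>, <b',b'>}.  The
heterozygote likelihood is the binomial C(n,k)(1/2)^n over the n reads
showing b or b'; a homozygote <x,x> multiplies (1-P_s) for reads agreeing
with x and P_s/3 for the others, with P_s = 10^(-q/10) from the PHRED
quality.  MAQ-style priors put mass r on the heterozygote and r^2 on the
non-reference homozygote (r = 0.001 by default).  A site whose maximum
posterior genotype differs from the reference homozygote is a tentative
SNP, then filtered by read depth (>= Cover/5) and by the posterior-ratio
score (P_1 + P_2)/P_max (lower is better).

InDels are read off the alignments: per-read insertion/deletion events are
pooled per site and reported when their summed quality exceeds half the
average per-column quality mass of the nearby sites.

Two code paths produce identical calls: a per-column scalar path
(build_pileup / genotype_posterior), and a vectorized whole-reference path
(call_variants) used by the benchmark pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import gammaln

from ._codec import encode
from .errors import ParameterError
from .io_formats import ReferenceSeq, Variant

__all__ = [
    "CallParams",
    "PileupColumn",
    "GenotypeCall",
    "error_prob",
    "build_pileup",
    "genotype_posterior",
    "depth_filter",
    "score_filter",
    "call_insertion",
    "call_deletion",
    "call_variants",
]

_BASES = "ACGT"
MAX_ERROR_PROB = 0.75  # a q=0 base must stay uninformative on a 4-letter alphabet


@dataclass(frozen=True)
class CallParams:
    r: float = 0.001  # prior probability of a heterozygous site
    depth_frac: float = 0.2  # depth filter threshold as a fraction of Cover
    # reference-homozygote posterior odds cutoff; 0.01 requires variant
    # posterior >= ~0.99, the usual Q20 consensus-quality bar
    score_threshold: float = 0.01
    flank_window: int = 10  # columns each side used as the InDel comparator
    indel_support_frac: float = 0.5  # fraction of local quality mass an InDel must carry
    indel_mask_window: int = 5  # no SNP calls this close to multi-read InDel evidence
    require_both_filters: bool = True


@dataclass
class PileupColumn:
    ref_name: str
    pos: int  # 0-based
    ref_base: str
    bases: str = ""  # observed bases, one char per covering read
    quals: list[int] = field(default_factory=list)
    insertions: list[tuple[str, float]] = field(default_factory=list)  # (seq, mean qual)
    deletions: list[tuple[int, float]] = field(default_factory=list)  # (length, qual mass)

    @property
    def depth(self) -> int:
        return len(self.bases)


@dataclass
class GenotypeCall:
    ref_name: str
    pos: int
    ref_base: str
    b: str
    b2: str
    k: int
    n: int
    posteriors: np.ndarray  # P(<b,b>|D), P(<b,b'>|D), P(<b',b'>|D)
    called: int  # argmax index into posteriors
    is_snp: bool
    alt: str
    snp_score: float
    depth: int
    passed_depth: bool = True
    passed_score: bool = True


def error_prob(q) -> np.ndarray | float:
    """PHRED error probability P_s = 10^(-q/10), clamped to <= 0.75."""
    q = np.asarray(q)
    if (q < 0).any():
        raise ParameterError("negative PHRED score")
    p = np.minimum(10.0 ** (-q / 10.0), MAX_ERROR_PROB)
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# pileup construction (scalar path)


def _walk(aln) -> Iterator[tuple[str, int, int, int]]:
    """Yield (op, length, read_offset, ref_offset) for each CIGAR op."""
    i = j = 0
    for op, ln in aln.cigar:
        yield op, ln, i, j
        if op in ("M", "I"):
            i += ln
        if op in ("M", "D"):
            j += ln


def _aligned_columns(aln, ref_codes: np.ndarray, read_codes: np.ndarray):
    """(read_idx, ref_pos) arrays of M columns, terminal mismatch runs trimmed.

    A run of consecutive mismatches touching either aligned end of a read is
    an alignment artifact (an InDel or clipped placement the extension could
    not represent), not independent base evidence; those columns are removed
    before they enter the pileup.
    """
    ridx: list[np.ndarray] = []
    rpos: list[np.ndarray] = []
    for op, ln, i, j in _walk(aln):
        if op == "M":
            ridx.append(np.arange(i, i + ln, dtype=np.int64))
            rpos.append(np.arange(aln.ref_start + j, aln.ref_start + j + ln, dtype=np.int64))
    if not ridx:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    read_idx = np.concatenate(ridx)
    ref_pos = np.concatenate(rpos)
    ok = (ref_pos >= 0) & (ref_pos < len(ref_codes))
    read_idx, ref_pos = read_idx[ok], ref_pos[ok]
    if len(read_idx) == 0:
        return read_idx, ref_pos
    mm = read_codes[read_idx] != ref_codes[ref_pos]
    lo = int(np.argmin(mm)) if not mm.all() else len(mm)
    hi = len(mm) - int(np.argmin(mm[::-1])) if not mm.all() else 0
    return read_idx[lo:hi], ref_pos[lo:hi]


def build_pileup(alignments, refs: Sequence[ReferenceSeq]) -> Iterator[PileupColumn]:
    """One column per covered reference position, in (ref, position) order.

    Insertions attach to the column of the base preceding them; a deletion
    contributes an event to each deleted column.  Unsorted input is sorted
    internally.  Intended for modest data sizes; the benchmark pipeline uses
    the vectorized path in :func:`call_variants`.
    """
    seqs = {r.name: r.sequence for r in refs}
    ref_codes = {r.name: encode(r.sequence) for r in refs}
    cols: dict[tuple[str, int], PileupColumn] = {}

    def col(ref_name: str, pos: int) -> PileupColumn:
        key = (ref_name, pos)
        if key not in cols:
            cols[key] = PileupColumn(ref_name, pos, seqs[ref_name][pos])
        return cols[key]

    for a in alignments:
        if not a.mapped:
            continue
        read_idx, ref_pos = _aligned_columns(a, ref_codes[a.ref_name], encode(a.bases))
        for i, pos in zip(read_idx.tolist(), ref_pos.tolist()):
            c = col(a.ref_name, pos)
            c.bases += a.bases[i]
            c.quals.append(int(a.quals[i]))
        n_ops = len(a.cigar)
        for oi, (op, ln, i, j) in enumerate(_walk(a)):
            if op == "I":
                if 0 < oi < n_ops - 1:  # interior insertions only
                    anchor = a.ref_start + j - 1
                    if anchor >= 0:
                        mq = float(np.mean(a.quals[i : i + ln]))
                        col(a.ref_name, anchor).insertions.append((a.bases[i : i + ln], mq))
            elif op == "D":
                qm = float(np.mean([a.quals[max(i - 1, 0)], a.quals[min(i, len(a.quals) - 1)]]))
                for t in range(ln):
                    col(a.ref_name, a.ref_start + j + t).deletions.append((ln, qm))
    for key in sorted(cols):
        yield cols[key]


# ---------------------------------------------------------------------------
# genotype model (scalar path)


def _top_two(counts: np.ndarray, ref_code: int) -> tuple[int, int]:
    # most frequent base; ties prefer the reference base, then A<C<G<T
    key = counts * 16 + (np.arange(4) == ref_code) * 4 + (3 - np.arange(4))
    b = int(np.argmax(key))
    key[b] = -1
    b2 = int(np.argmax(key))
    if counts[b2] == 0:
        if ref_code < 4 and ref_code != b:
            b2 = ref_code
        else:
            b2 = next(c for c in range(4) if c != b)
    return b, b2


def _log_priors(r: float, b: int, b2: int, ref_code: int) -> np.ndarray:
    hom_ref = math.log(1.0 - r - r * r)
    het = math.log(r)
    hom_alt = 2.0 * math.log(r)
    if b == ref_code:
        return np.array([hom_ref, het, hom_alt])
    if b2 == ref_code:
        return np.array([hom_alt, het, hom_ref])
    return np.array([hom_alt, het, hom_alt])  # reference base not observed


def genotype_posterior(col: PileupColumn, r: float = 0.001) -> GenotypeCall | None:
    """Posterior over {<b,b>, <b,b'>, <b',b'>} for one pileup column."""
    if col.depth == 0:
        return None
    codes = encode(col.bases)
    quals = np.asarray(col.quals, dtype=float)
    counts = np.bincount(codes[codes < 4], minlength=4)
    ref_code = int(encode(col.ref_base)[0])
    b, b2 = _top_two(counts, ref_code)
    sel_b = codes == b
    sel_b2 = codes == b2
    k = int(counts[b])
    n = k + int(counts[b2])
    ps = error_prob(quals)
    log_ok = np.log1p(-ps)
    log_err = np.log(ps / 3.0)
    ll_hom_b = float(log_ok[sel_b].sum() + log_err[sel_b2].sum())
    ll_hom_b2 = float(log_ok[sel_b2].sum() + log_err[sel_b].sum())
    ll_het = float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1) - n * math.log(2.0))
    logp_raw = np.array([ll_hom_b, ll_het, ll_hom_b2]) + _log_priors(r, b, b2, ref_code)
    logp = logp_raw - logp_raw.max()
    post = np.exp(logp)
    post /= post.sum()
    called = int(np.argmax(post))
    is_snp = not (called == 0 and b == ref_code) and not (called == 2 and b2 == ref_code)
    if called == 1:  # heterozygote: report the non-reference member
        alt_code = b2 if b == ref_code else b
    else:
        alt_code = b if called == 0 else b2
    # reliability score: posterior odds that the site is in fact the
    # reference homozygote (lower = more reliable SNP); quality-aware via
    # the homozygote likelihoods, unlike the quality-blind het binomial
    if b == ref_code:
        p_ref = float(post[0])
    elif b2 == ref_code:
        p_ref = float(post[2])
    else:
        # reference base unobserved: score it as an explicit 4th hypothesis
        ll_ref = float(log_err[sel_b | sel_b2].sum())
        lr = np.concatenate([logp_raw, [ll_ref + math.log(1.0 - r - r * r)]])
        lr -= lr.max()
        er = np.exp(lr)
        p_ref = float(er[3] / er.sum())
    score = p_ref / max(1.0 - p_ref, 1e-300)
    return GenotypeCall(
        ref_name=col.ref_name,
        pos=col.pos,
        ref_base=col.ref_base,
        b=_BASES[b],
        b2=_BASES[b2],
        k=k,
        n=n,
        posteriors=post,
        called=called,
        is_snp=is_snp,
        alt=_BASES[alt_code],
        snp_score=score,
        depth=col.depth,
    )


def depth_filter(depth: int, mean_cover: float, depth_frac: float = 0.2) -> bool:
    """Pass iff depth >= Cover * depth_frac (inclusive); default Cover/5."""
    if mean_cover <= 0:
        raise ParameterError("mean coverage must be positive")
    return depth >= mean_cover * depth_frac


def score_filter(call: GenotypeCall, threshold: float = 0.1) -> bool:
    """Pass iff the SNP reliability score is <= threshold.

    The score is the posterior odds of the reference homozygote,
    P(<ref,ref>|D) / (1 - P(<ref,ref>|D)); lower = more reliable.  At the
    default threshold 0.1 a call needs P(variant) >= 10/11.
    """
    return call.snp_score <= threshold


# ---------------------------------------------------------------------------
# InDel calls (scalar path)


def _flank_mean(qsum: dict[int, float], positions: Iterable[int]) -> float:
    vals = [qsum.get(p, 0.0) for p in positions]
    return float(np.mean(vals)) if vals else 0.0


def call_insertion(
    col: PileupColumn,
    flank_qsums: Sequence[float],
    params: CallParams = CallParams(),
) -> Variant | None:
    """Insertion call at one anchor column.

    ``flank_qsums`` are the per-column base-quality sums of the nearby
    columns (up to ``flank_window`` each side, InDel columns excluded).
    The most frequent inserted sequence is reported iff the summed per-read
    insertion quality exceeds ``indel_support_frac`` of the mean flank mass.
    """
    if not col.insertions:
        return None
    stat = float(sum(q for _, q in col.insertions))
    comparator = params.indel_support_frac * (float(np.mean(flank_qsums)) if len(flank_qsums) else 0.0)
    if not stat > comparator:
        return None
    seqs: dict[str, int] = {}
    for s, _ in col.insertions:
        seqs[s] = seqs.get(s, 0) + 1
    ranked = sorted(seqs.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None  # conflicting sequences tie: no call
    return Variant(
        chrom=col.ref_name,
        pos=col.pos,
        type="INS",
        ref="",
        alt=ranked[0][0],
        score=stat,
        depth=len(col.insertions),
    )


def call_deletion(
    cols: Sequence[PileupColumn],
    flank_qsums: Sequence[float],
    params: CallParams = CallParams(),
) -> Variant | None:
    """Deletion call over a maximal run of consecutive deleted columns."""
    cols = [c for c in cols if c.deletions]
    if not cols:
        return None
    # each supporting read contributes once per run: count events on the first
    # column of each per-read deletion span
    start = cols[0].pos
    events: list[float] = []
    for c in cols:
        for ln, qm in c.deletions:
            events.append(qm)
    # a read deleting g bases appears on each of its g columns; normalize
    stat = float(sum(qm / ln for c in cols for ln, qm in c.deletions))
    comparator = params.indel_support_frac * (float(np.mean(flank_qsums)) if len(flank_qsums) else 0.0)
    if not stat > comparator:
        return None
    # modal deleted length among the events at the run start
    lens = [ln for ln, _ in cols[0].deletions]
    modal = min(sorted(set(lens)), key=lambda g: (-lens.count(g), g))
    n_reads = len(cols[0].deletions)
    return Variant(
        chrom=cols[0].ref_name,
        pos=start,
        type="DEL",
        ref="?" * modal,  # caller fills the actual deleted sequence
        alt="",
        score=stat,
        depth=n_reads,
    )


# ---------------------------------------------------------------------------
# vectorized whole-reference pipeline


def call_variants(
    alignments,
    refs: Sequence[ReferenceSeq],
    params: CallParams = CallParams(),
) -> tuple[list[Variant], float]:
    """Call SNPs and InDels from accepted alignments against ``refs``.

    Returns (calls, mean_cover) where mean_cover is the average coverage
    Cover = (total aligned read bases) / (reference positions with >= 1
    aligned base), the basis of the depth filter.
    """
    ref_ix = {r.name: i for i, r in enumerate(refs)}
    lens = [r.length for r in refs]
    pos_chunks: list[list[np.ndarray]] = [[] for _ in refs]
    code_chunks: list[list[np.ndarray]] = [[] for _ in refs]
    qual_chunks: list[list[np.ndarray]] = [[] for _ in refs]
    ins_events: dict[tuple[int, int], list[tuple[str, float]]] = {}
    del_events: dict[int, list[tuple[int, int, float]]] = {}  # ref -> (pos, len, qmass)

    all_ref_codes = [encode(r.sequence) for r in refs]
    for a in alignments:
        if not a.mapped:
            continue
        ri = ref_ix[a.ref_name]
        codes = encode(a.bases)
        quals = np.asarray(a.quals, dtype=np.int16)
        read_idx, ref_pos = _aligned_columns(a, all_ref_codes[ri], codes)
        pos_chunks[ri].append(ref_pos)
        code_chunks[ri].append(codes[read_idx])
        qual_chunks[ri].append(quals[read_idx])
        n_ops = len(a.cigar)
        for oi, (op, ln, i, j) in enumerate(_walk(a)):
            if op == "I" and 0 < oi < n_ops - 1:
                anchor = a.ref_start + j - 1
                if anchor >= 0:
                    mq = float(quals[i : i + ln].mean())
                    ins_events.setdefault((ri, anchor), []).append((a.bases[i : i + ln], mq))
            elif op == "D":
                qm = float(np.mean([quals[max(i - 1, 0)], quals[min(i, len(quals) - 1)]]))
                del_events.setdefault(ri, []).append((a.ref_start + j, ln, qm))

    calls: list[Variant] = []
    total_bases = 0
    covered = 0
    per_ref: list[dict] = []
    for ri, ref in enumerate(refs):
        L = lens[ri]
        if pos_chunks[ri]:
            pos = np.concatenate(pos_chunks[ri])
            code = np.concatenate(code_chunks[ri])
            qual = np.concatenate(qual_chunks[ri]).astype(float)
        else:
            pos = np.empty(0, dtype=np.int64)
            code = np.empty(0, dtype=np.uint8)
            qual = np.empty(0, dtype=float)
        keep = (pos >= 0) & (pos < L)
        pos, code, qual = pos[keep], code[keep], qual[keep]
        ps = error_prob(qual) if len(qual) else np.empty(0)
        log_ok = np.log1p(-ps)
        log_err = np.log(ps / 3.0) if len(ps) else np.empty(0)
        C = np.zeros((4, L), dtype=np.int64)
        A = np.zeros((4, L))
        G = np.zeros((4, L))
        for c in range(4):
            sel = code == c
            if sel.any():
                C[c] = np.bincount(pos[sel], minlength=L)
                A[c] = np.bincount(pos[sel], weights=log_ok[sel], minlength=L)
                G[c] = np.bincount(pos[sel], weights=log_err[sel], minlength=L)
        qsum = np.bincount(pos, weights=qual, minlength=L) if len(pos) else np.zeros(L)
        depth = C.sum(axis=0)
        total_bases += int(depth.sum())
        covered += int((depth > 0).sum())
        per_ref.append(dict(C=C, A=A, G=G, qsum=qsum, depth=depth))

    mean_cover = total_bases / covered if covered else 0.0
    min_depth = mean_cover * params.depth_frac

    log_r = math.log(params.r)
    log_hom_ref = math.log(1.0 - params.r - params.r**2)
    for ri, ref in enumerate(refs):
        d = per_ref[ri]
        C, A, G, qsum, depth = d["C"], d["A"], d["G"], d["qsum"], d["depth"]
        L = lens[ri]
        R = encode(ref.sequence)
        # gap placement near an InDel is ambiguous and leaks systematic
        # mismatches into adjacent columns; mask SNP calling around any
        # column with InDel evidence from two or more reads
        indel_mask = np.zeros(L, dtype=bool)
        w = params.indel_mask_window
        for (eri, anchor), events in ins_events.items():
            if eri == ri and len(events) >= 2:
                indel_mask[max(0, anchor - w) : min(L, anchor + w + 1)] = True
        ev_count: dict[int, int] = {}
        for p, ln, _ in del_events.get(ri, []):
            for t in range(p, p + ln):
                ev_count[t] = ev_count.get(t, 0) + 1
        for p, cnt in ev_count.items():
            if cnt >= 2:
                indel_mask[max(0, p - w) : min(L, p + w + 1)] = True
        sites = np.flatnonzero((depth > 0) & (R < 4) & ~indel_mask)
        if len(sites):
            Cs = C[:, sites]
            key = Cs * 16 + (np.arange(4)[:, None] == R[sites][None, :]) * 4 + (3 - np.arange(4))[:, None]
            b = np.argmax(key, axis=0)
            key[b, np.arange(len(sites))] = -1
            b2 = np.argmax(key, axis=0)
            # b' defaults to the reference base (count 0) when unobserved
            no2 = Cs[b2, np.arange(len(sites))] == 0
            refc = R[sites].astype(np.int64)
            alt_default = np.where(refc != b, refc, (b + 1) % 4)
            b2 = np.where(no2, alt_default, b2)
            ar = np.arange(len(sites))
            k = Cs[b, ar]
            n = k + Cs[b2, ar]
            ll_het = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1) - n * math.log(2.0)
            ll_hom_b = A[b, sites] + G[b2, sites]
            ll_hom_b2 = A[b2, sites] + G[b, sites]
            pri_b = np.where(b == refc, log_hom_ref, 2 * log_r)
            pri_b2 = np.where(b2 == refc, log_hom_ref, 2 * log_r)
            # reference homozygote as an explicit hypothesis even when the
            # reference base is not among {b, b'}: every evidence read is
            # then an error under it
            ll_ref_unobs = G[b, sites] + G[b2, sites]
            logp_raw = np.stack([ll_hom_b + pri_b, ll_het + log_r, ll_hom_b2 + pri_b2])
            logp = logp_raw - logp_raw.max(axis=0, keepdims=True)
            post = np.exp(logp)
            post /= post.sum(axis=0, keepdims=True)
            called = np.argmax(post, axis=0)
            ref_unobs = (b != refc) & (b2 != refc)
            lr4 = np.concatenate(
                [logp_raw, (ll_ref_unobs + log_hom_ref)[None, :]], axis=0
            )
            lr4 -= lr4.max(axis=0, keepdims=True)
            er4 = np.exp(lr4)
            p_ref4 = er4[3] / er4.sum(axis=0)
            p_ref = np.where(b == refc, post[0], np.where(b2 == refc, post[2], p_ref4))
            score = p_ref / np.maximum(1.0 - p_ref, 1e-300)
            hom_base = np.where(called == 0, b, b2)
            is_snp = np.where(called == 1, True, hom_base != refc)
            passed = is_snp.astype(bool)
            if params.require_both_filters:
                passed &= depth[sites] >= min_depth
                passed &= score <= params.score_threshold
            else:
                passed &= (depth[sites] >= min_depth) | (score <= params.score_threshold)
            alt_het = np.where(b == refc, b2, b)
            alt = np.where(called == 1, alt_het, hom_base)
            for t in np.flatnonzero(passed):
                site = int(sites[t])
                zyg = "het" if called[t] == 1 else "hom"
                calls.append(
                    Variant(
                        chrom=ref.name,
                        pos=site,
                        type="SNP",
                        ref=ref.sequence[site],
                        alt=_BASES[int(alt[t])],
                        score=float(score[t]),
                        depth=int(depth[site]),
                        zygosity=zyg,
                    )
                )

        # insertions
        for (eri, anchor), events in sorted(ins_events.items()):
            if eri != ri:
                continue
            stat = sum(q for _, q in events)
            fl = _flank_positions(anchor + 0.5, [], params.flank_window, L)
            comparator = params.indel_support_frac * (qsum[fl].mean() if len(fl) else 0.0)
            if not stat > comparator:
                continue
            seq_counts: dict[str, int] = {}
            for s, _ in events:
                seq_counts[s] = seq_counts.get(s, 0) + 1
            ranked = sorted(seq_counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                continue
            calls.append(
                Variant(
                    chrom=ref.name,
                    pos=anchor,
                    type="INS",
                    ref="",
                    alt=ranked[0][0],
                    score=float(stat),
                    depth=len(events),
                )
            )

        # deletions: maximal runs of deleted columns
        events = del_events.get(ri, [])
        if events:
            marked = np.zeros(L, dtype=bool)
            for p, ln, _ in events:
                marked[max(0, p) : min(L, p + ln)] = True
            idx = np.flatnonzero(marked)
            if len(idx):
                breaks = np.flatnonzero(np.diff(idx) > 1)
                run_starts = np.concatenate([[0], breaks + 1])
                run_ends = np.concatenate([breaks, [len(idx) - 1]])
                for rs, re in zip(run_starts, run_ends):
                    lo, hi = int(idx[rs]), int(idx[re]) + 1
                    sup = [(p, ln, qm) for p, ln, qm in events if p < hi and p + ln > lo]
                    stat = sum(qm for _, _, qm in sup)
                    fl = _flank_positions(None, list(range(lo, hi)), params.flank_window, L)
                    comparator = params.indel_support_frac * (qsum[fl].mean() if len(fl) else 0.0)
                    if not stat > comparator:
                        continue
                    # ragged per-read alignments can stretch the marked run;
                    # report the modal deleted span among the supporting reads
                    span_votes: dict[tuple[int, int], int] = {}
                    for p, ln, _ in sup:
                        span_votes[(p, ln)] = span_votes.get((p, ln), 0) + 1
                    (dpos, dlen), _votes = min(
                        span_votes.items(), key=lambda kv: (-kv[1], kv[0])
                    )
                    dpos, dlen = max(0, dpos), min(dlen, L - max(0, dpos))
                    calls.append(
                        Variant(
                            chrom=ref.name,
                            pos=dpos,
                            type="DEL",
                            ref=ref.sequence[dpos : dpos + dlen],
                            alt="",
                            score=float(stat),
                            depth=len(sup),
                        )
                    )
    calls.sort(key=lambda v: (v.chrom, v.pos, v.type))
    return calls, mean_cover


def _flank_positions(center: float | None, exclude: list[int], w: int, L: int) -> np.ndarray:
    """Column indices of the comparator window, InDel columns excluded."""
    if center is not None:  # insertion between floor(center) and ceil(center)
        a = int(math.floor(center))
        left = range(max(0, a - w + 1), a + 1)
        right = range(a + 1, min(L, a + 1 + w))
        return np.fromiter(list(left) + list(right), dtype=np.int64)
    lo, hi = exclude[0], exclude[-1] + 1
    left = range(max(0, lo - w), lo)
    right = range(hi, min(L, hi + w))
    return np.fromiter(list(left) + list(right), dtype=np.int64)
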