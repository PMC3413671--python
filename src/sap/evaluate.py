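"""Benchmark metrics: captured-read fraction, variant accuracy TP/P and
coverage TP/T, and the end-to-end simulate -> map -> call benchmark driver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .errors import ConsistencyError
from .index import build_index
from .io_formats import ReferenceSeq, Variant
from .mapper import MapParams, map_read, map_reads
from .predictor import CallParams, call_variants
from .simulator import SimulationConfig, simulate_dataset

__all__ = [
    "BenchmarkReport",
    "captured_fraction",
    "left_normalize",
    "match_variants",
    "accuracy_coverage",
    "run_cell",
    "run_benchmark",
]


@dataclass
class BenchmarkReport:
    """Metrics of one simulated cell (read length x coverage x mode)."""

    read_len: int
    coverage: float
    mode: str
    captured: float
    tp: dict
    p: dict
    t: dict
    n_reads: int = 0

    def accuracy(self, vtype: str) -> float:
        return accuracy_coverage(self.tp[vtype], self.p[vtype], self.t[vtype])[0]

    def cov(self, vtype: str) -> float:
        return accuracy_coverage(self.tp[vtype], self.p[vtype], self.t[vtype])[1]


def captured_fraction(alignments, reads) -> float:
    """Fraction of reads with an accepted (mapped) alignment."""
    ids = {r.id for r in reads}
    mapped = 0
    seen = set()
    for a in alignments:
        if a.read_id not in ids:
            raise ConsistencyError(f"alignment for unknown read {a.read_id!r}")
        seen.add(a.read_id)
        if a.mapped:
            mapped += 1
    return mapped / len(reads) if reads else 0.0


def left_normalize(v: Variant, seq: str) -> Variant:
    """Shift an InDel to its leftmost equivalent position (repeat context)."""
    if v.type == "DEL":
        pos, run = v.pos, v.ref
        while pos > 0 and seq[pos - 1] == run[-1]:
            pos -= 1
            run = seq[pos] + run[:-1]
        return replace(v, pos=pos, ref=run) if pos != v.pos else v
    if v.type == "INS":
        pos, ins = v.pos, v.alt
        while pos >= 1 and seq[pos] == ins[-1]:
            ins = ins[-1] + ins[:-1]
            pos -= 1
        return replace(v, pos=pos, alt=ins) if pos != v.pos else v
    return v


def match_variants(
    calls: list[Variant],
    truth: list[Variant],
    indel_pos_tolerance: int = 2,
    refs: list[ReferenceSeq] | None = None,
) -> tuple[list[Variant], list[Variant], list[Variant]]:
    """(TP, FP, FN) with allele-aware SNP matching and tolerant InDel matching.

    A SNP matches on exact position and alt allele.  An InDel matches a truth
    variant of the same type and length within ``indel_pos_tolerance`` bp
    (both sets left-normalized first when ``refs`` is given).  Each truth
    variant is consumed at most once.
    """
    seqs = {r.name: r.sequence for r in refs} if refs else {}

    def norm(v: Variant) -> Variant:
        return left_normalize(v, seqs[v.chrom]) if v.chrom in seqs else v

    calls_n = [norm(v) for v in calls]
    truth_n = [norm(v) for v in truth]
    consumed = [False] * len(truth_n)
    snp_truth = {
        (t.chrom, t.pos, t.alt): i for i, t in enumerate(truth_n) if t.type == "SNP"
    }
    tp: list[Variant] = []
    fp: list[Variant] = []
    order = sorted(range(len(calls_n)), key=lambda i: (calls_n[i].chrom, calls_n[i].pos))
    for ci in order:
        c = calls_n[ci]
        if c.type == "SNP":
            ti = snp_truth.get((c.chrom, c.pos, c.alt))
            if ti is not None and not consumed[ti]:
                consumed[ti] = True
                tp.append(calls[ci])
            else:
                fp.append(calls[ci])
            continue
        best, best_d = None, None
        for ti, t in enumerate(truth_n):
            if consumed[ti] or t.type != c.type or t.chrom != c.chrom:
                continue
            if t.length != c.length:
                continue
            d = abs(t.pos - c.pos)
            if d <= indel_pos_tolerance and (best_d is None or d < best_d):
                best, best_d = ti, d
        if best is not None:
            consumed[best] = True
            tp.append(calls[ci])
        else:
            fp.append(calls[ci])
    fn = [truth[i] for i in range(len(truth)) if not consumed[i]]
    return tp, fp, fn


def accuracy_coverage(tp: int, p: int, t: int) -> tuple[float, float]:
    """(TP/P, TP/T); accuracy is NaN when nothing was predicted."""
    if min(tp, p, t) < 0 or tp > p or tp > t:
        raise ConsistencyError(f"inconsistent counts TP={tp} P={p} T={t}")
    acc = tp / p if p else math.nan
    cov = tp / t if t else math.nan
    return acc, cov


def _count_by_type(variants) -> dict:
    out = {"SNP": 0, "INS": 0, "DEL": 0}
    for v in variants:
        out[v.type] = out.get(v.type, 0) + 1
    return out


def run_cell(
    ref: ReferenceSeq,
    index,
    read_len: int,
    coverage: float,
    seed: int,
    sim_cfg: SimulationConfig | None = None,
    map_params: MapParams = MapParams(),
    call_params: CallParams = CallParams(),
    modes: tuple[str, ...] = ("fast", "slow"),
) -> dict[str, BenchmarkReport]:
    """Simulate one dataset and evaluate it in the requested mapping modes.

    SlowMap reuses the FastMap alignments and retries only the reads FastMap
    left unmapped, which is exactly the slow-mode mapping semantics.
    """
    base = sim_cfg or SimulationConfig()
    cfg = replace(base, read_len=read_len, coverage=coverage, seed=seed)
    ds = simulate_dataset(ref, cfg)
    refs = [ref]
    reports: dict[str, BenchmarkReport] = {}
    fast = map_reads(ds.reads, index, "fast", map_params)
    by_mode = {"fast": fast}
    if "slow" in modes:
        slow = list(fast)
        for i, a in enumerate(fast):
            if not a.mapped:
                slow[i] = map_read(ds.reads[i], index, "slow", map_params)
        by_mode["slow"] = slow
    for mode in modes:
        alignments = by_mode[mode]
        calls, _cover = call_variants(alignments, refs, call_params)
        tp, fp, fn = match_variants(calls, ds.truth, refs=refs)
        reports[mode] = BenchmarkReport(
            read_len=read_len,
            coverage=coverage,
            mode=mode,
            captured=captured_fraction(alignments, ds.reads),
            tp=_count_by_type(tp),
            p=_count_by_type(calls),
            t=_count_by_type(ds.truth),
            n_reads=len(ds.reads),
        )
    return reports


def run_benchmark(
    ref: ReferenceSeq,
    cells: list[tuple[int, float]],
    replicates: int = 3,
    seed: int = 17,
    sim_cfg: SimulationConfig | None = None,
    map_params: MapParams = MapParams(),
    call_params: CallParams = CallParams(),
    modes: tuple[str, ...] = ("fast", "slow"),
    k: int = 15,
) -> pd.DataFrame:
    """Replicated benchmark over a grid of (read length, coverage) cells.

    Returns one row per cell x replicate x mode with captured fraction and
    per-type TP/P/T counts; metrics are averaged over replicates downstream.
    A failed cell is recorded with NaNs and the run continues.
    """
    index = build_index([ref], k=k)
    rows = []
    for read_len, coverage in cells:
        for rep in range(replicates):
            cell_seed = (seed * 1_000_003 + read_len * 101 + int(coverage * 7919) + rep) % (2**31)
            try:
                reports = run_cell(
                    ref, index, read_len, coverage, cell_seed,
                    sim_cfg, map_params, call_params, modes,
                )
            except Exception as exc:  # record and continue per the contract
                for mode in modes:
                    rows.append(dict(read_len=read_len, coverage=coverage, rep=rep,
                                     mode=mode, failed=str(exc)))
                continue
            for mode, rep_out in reports.items():
                row = dict(
                    read_len=read_len,
                    coverage=coverage,
                    rep=rep,
                    mode=mode,
                    failed="",
                    captured=rep_out.captured,
                    n_reads=rep_out.n_reads,
                )
                for vt in ("SNP", "INS", "DEL"):
                    acc, cov = accuracy_coverage(
                        rep_out.tp[vt], rep_out.p[vt], rep_out.t[vt]
                    )
                    row[f"{vt.lower()}_tp"] = rep_out.tp[vt]
                    row[f"{vt.lower()}_p"] = rep_out.p[vt]
                    row[f"{vt.lower()}_t"] = rep_out.t[vt]
                    row[f"{vt.lower()}_acc"] = acc
                    row[f"{vt.lower()}_cov"] = cov
                rows.append(row)
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged metrics per (read_len, coverage, mode)."""
    metrics = [c for c in table.columns
               if c.endswith(("_acc", "_cov")) or c == "captured"]
    return (
        table[table["failed"] == ""]
        .groupby(["read_len", "coverage", "mode"])[metrics]
        .mean()
        .reset_index()
    )
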