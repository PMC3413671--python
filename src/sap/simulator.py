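"""Synthetic exon-capture sequencing data with known injected variants.

The generator emulates a targeted (exon-capture style) single-end sequencing
experiment: SNPs and small InDels are injected into a reference copy at
fixed per-base rates (defaults 0.02% and 0.009%), the mutated copy is
partitioned into captured target regions, each region is cut into random
fragments of 300-1500 bp with Poisson counts, and one single-end read is
sequenced from a uniformly chosen end (5' prefix or reverse-complemented 3'
suffix) of each fragment with a 2% base error rate.  The injected variants
are returned as ground truth in ORIGINAL reference coordinates, so variant
calls made against the original reference are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._codec import decode, encode, revcomp_codes
from .errors import ParameterError
from .io_formats import Read, ReferenceSeq, Variant

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "random_reference",
    "mutate_reference",
    "apply_variants",
    "make_regions",
    "fragment_regions",
    "generate_reads",
    "simulate_dataset",
]

_Q_HI = 30  # high-quality tier, P_s = 0.001
_Q_LO = 6  # low-quality tier, P_s ~= 0.251


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    The default rates are the benchmark recipe: SNPs at 2e-4/base, InDels at
    9e-5/base (uniform 1-5 bp, half insertions), fragments of 300-1500 bp
    with Poisson counts per target region, and a 2% mean base error rate.
    ``quality_model`` "two-tier" draws each base quality from {Q30, Q6} with
    the low tier weighted so the PHRED-implied mean error equals
    ``error_rate`` and errors are generated at the per-base implied
    probability (calibrated qualities); "constant" assigns ``quality``
    everywhere and flips bases at a flat ``error_rate``.
    """

    read_len: int = 75
    coverage: float = 5.0
    snp_rate: float = 2e-4
    indel_rate: float = 9e-5
    indel_len_range: tuple[int, int] = (1, 5)
    ins_fraction: float = 0.5
    frag_len_range: tuple[int, int] = (300, 1500)
    error_rate: float = 0.02
    quality_model: str = "two-tier"  # or "constant"
    quality: int = 20  # used by the constant model
    ploidy_model: str = "haploid"  # or "diploid-5050"
    region_len_median: float = 1000.0
    region_len_sigma: float = 0.75
    region_min_len: int = 200
    seed: int = 0

    def __post_init__(self):
        for rate in (self.snp_rate, self.indel_rate, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"rate {rate} outside [0, 1]")
        if self.read_len < 1:
            raise ParameterError("read length must be positive")


@dataclass
class SimulatedDataset:
    reads: list[Read]
    truth: list[Variant]
    mutated: ReferenceSeq  # all variants applied
    haplotypes: list[ReferenceSeq]
    regions: list[tuple[int, int]]  # target regions on the mutated sequence
    config: SimulationConfig


def random_reference(length: int, seed: int = 0, name: str = "chr1") -> ReferenceSeq:
    """A uniform-composition random reference sequence."""
    rng = np.random.default_rng(seed)
    return ReferenceSeq(name, decode(rng.integers(0, 4, size=length).astype(np.uint8)))


# ---------------------------------------------------------------------------
# variant injection


def _footprint(v: Variant) -> tuple[int, int]:
    if v.type == "SNP":
        return v.pos, v.pos + 1
    if v.type == "DEL":
        return v.pos, v.pos + len(v.ref)
    return v.pos, v.pos + 1  # INS occupies the anchor base


def mutate_reference(
    ref: ReferenceSeq, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[ReferenceSeq, list[Variant]]:
    """Inject SNPs and InDels at the configured per-base rates.

    Overlapping events are re-drawn at fresh positions.  Truth positions are
    ORIGINAL reference coordinates; the returned sequence has every variant
    applied (the "all variants" haplotype).
    """
    L = ref.length
    seq = ref.sequence
    n_snp = rng.binomial(L, cfg.snp_rate)
    n_indel = rng.binomial(L, cfg.indel_rate)
    occupied = np.zeros(L + 2, dtype=bool)
    variants: list[Variant] = []
    lo_len, hi_len = cfg.indel_len_range

    def reserve(a: int, b: int) -> bool:
        a, b = max(0, a), min(L + 2, b)
        if occupied[a:b].any():
            return False
        occupied[a:b] = True
        return True

    def zygosity() -> str:
        if cfg.ploidy_model == "haploid":
            return "hom"
        return "het" if rng.random() < 0.5 else "hom"

    for _ in range(n_indel):
        for _attempt in range(1000):
            g = int(rng.integers(lo_len, hi_len + 1))
            is_ins = rng.random() < cfg.ins_fraction
            if is_ins:
                p = int(rng.integers(0, L))
                if "N" in seq[p : p + 1] or not reserve(p, p + 2):
                    continue
                alt = decode(rng.integers(0, 4, size=g).astype(np.uint8))
                variants.append(Variant(ref.name, p, "INS", "", alt, zygosity=zygosity()))
            else:
                p = int(rng.integers(1, L - g))  # keep an anchor base on each side
                run = seq[p : p + g]
                if "N" in run or not reserve(p - 1, p + g + 1):
                    continue
                variants.append(Variant(ref.name, p, "DEL", run, "", zygosity=zygosity()))
            break
        else:
            raise ParameterError("could not place InDel without overlap; rates too high")

    for _ in range(n_snp):
        for _attempt in range(1000):
            p = int(rng.integers(0, L))
            base = seq[p]
            if base == "N" or not reserve(p, p + 1):
                continue
            alt = "ACGT".replace(base, "")[int(rng.integers(0, 3))]
            variants.append(Variant(ref.name, p, "SNP", base, alt, zygosity=zygosity()))
            break
        else:
            raise ParameterError("could not place SNP without overlap; rates too high")

    variants.sort(key=lambda v: v.pos)
    return apply_variants(ref, variants), variants


def apply_variants(ref: ReferenceSeq, variants: Sequence[Variant]) -> ReferenceSeq:
    """Splice a sorted, non-overlapping variant set into ``ref``."""
    seq = ref.sequence
    parts: list[str] = []
    cur = 0
    for v in sorted(variants, key=lambda v: v.pos):
        if v.type == "SNP":
            parts.append(seq[cur : v.pos])
            parts.append(v.alt)
            cur = v.pos + 1
        elif v.type == "DEL":
            parts.append(seq[cur : v.pos])
            cur = v.pos + len(v.ref)
        else:  # INS after pos
            parts.append(seq[cur : v.pos + 1])
            parts.append(v.alt)
            cur = v.pos + 1
    parts.append(seq[cur:])
    return ReferenceSeq(ref.name, "".join(parts))


# ---------------------------------------------------------------------------
# fragmentation and read generation


def make_regions(
    length: int, cfg: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Partition [0, length) into contiguous capture-target regions."""
    regions = []
    cur = 0
    mu = np.log(cfg.region_len_median)
    while cur < length:
        ln = int(np.exp(rng.normal(mu, cfg.region_len_sigma)))
        ln = max(cfg.region_min_len, ln)
        regions.append((cur, min(length, cur + ln)))
        cur += ln
    return regions


def _expected_read_len(region_len: int, cfg: SimulationConfig) -> float:
    fmin, fmax = cfg.frag_len_range
    flens = np.minimum(np.arange(fmin, fmax + 1), region_len)
    return float(np.minimum(cfg.read_len, flens).mean())


def fragment_regions(
    regions: Sequence[tuple[int, int]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    coverage: float | None = None,
    seq_len: int | None = None,
) -> list[tuple[int, int]]:
    """Cut each target region into random fragments with Poisson counts.

    Fragment lengths are drawn uniformly from the configured range and
    clipped to the region (a region shorter than the minimum fragment
    length yields fragments of the full region length).  The per-region
    Poisson mean is chosen so the single-end reads (one per fragment)
    realize the target read coverage:
    lambda = coverage * |region| / E[min(read_len, fragment_len, |region|)].
    """
    cov = cfg.coverage if coverage is None else coverage
    fmin, fmax = cfg.frag_len_range
    fragments: list[tuple[int, int]] = []
    for start, end in regions:
        rlen = end - start
        if rlen <= 0:
            continue
        lam = cov * rlen / _expected_read_len(rlen, cfg)
        count = rng.poisson(lam)
        if count == 0:
            continue
        flens = np.minimum(rng.integers(fmin, fmax + 1, size=count), rlen)
        starts = start + (rng.random(count) * (rlen - flens + 1)).astype(np.int64)
        fragments.extend(zip(starts.tolist(), flens.tolist()))
    return fragments


def _qualities(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.quality_model == "constant":
        return np.full(n, cfg.quality, dtype=np.int16)
    ps_hi, ps_lo = 10.0 ** (-_Q_HI / 10), 10.0 ** (-_Q_LO / 10)
    p_lo = min(1.0, max(0.0, (cfg.error_rate - ps_hi) / (ps_lo - ps_hi)))
    return np.where(rng.random(n) < p_lo, _Q_LO, _Q_HI).astype(np.int16)


def generate_reads(
    fragments: Sequence[tuple[int, int]],
    source: ReferenceSeq,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    id_prefix: str = "sim",
) -> list[Read]:
    """One single-end read per fragment, from a uniformly chosen end.

    5' end = forward prefix of the fragment; 3' end = reverse complement of
    the fragment suffix.  Base errors are injected per base (substitution to
    a uniform different base); the read id encodes the origin as
    ``prefix:source:fragstart:fragend:strand:serial``.
    """
    codes_all = encode(source.sequence)
    reads: list[Read] = []
    for serial, (fs, flen) in enumerate(fragments):
        eff = min(cfg.read_len, flen)
        frag = codes_all[fs : fs + flen]
        if rng.random() < 0.5:
            codes = frag[:eff].copy()
            strand = "5p"
        else:
            codes = revcomp_codes(frag)[:eff].copy()
            strand = "3p"
        quals = _qualities(eff, cfg, rng)
        if cfg.error_rate == 0.0:
            err_p = np.zeros(eff)
        elif cfg.quality_model == "constant":
            err_p = np.full(eff, cfg.error_rate)
        else:
            err_p = 10.0 ** (-quals / 10.0)
        err = rng.random(eff) < err_p
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            codes[err] = (codes[err] + shift) % 4
        reads.append(
            Read(
                f"{id_prefix}:{source.name}:{fs}:{fs + flen}:{strand}:{serial}",
                decode(codes),
                quals,
            )
        )
    return reads


def simulate_dataset(ref: ReferenceSeq, cfg: SimulationConfig) -> SimulatedDataset:
    """Full benchmark recipe: mutate, partition, fragment, sequence.

    Deterministic under a fixed ``cfg.seed``.  For the diploid model half
    the coverage is drawn from each haplotype (heterozygous variants on one
    only); the haploid default sequences the single mutated copy.
    """
    rng = np.random.default_rng(cfg.seed)
    mutated, truth = mutate_reference(ref, cfg, rng)
    if cfg.ploidy_model == "haploid":
        haplotypes = [mutated]
        coverages = [cfg.coverage]
    else:
        hom_only = [v for v in truth if v.zygosity == "hom"]
        haplotypes = [mutated, apply_variants(ref, hom_only)]
        coverages = [cfg.coverage / 2.0, cfg.coverage / 2.0]
    reads: list[Read] = []
    regions_out: list[tuple[int, int]] = []
    for hap_i, (hap, cov) in enumerate(zip(haplotypes, coverages)):
        regions = make_regions(hap.length, cfg, rng)
        if hap_i == 0:
            regions_out = regions
        frags = fragment_regions(regions, cfg, rng, coverage=cov, seq_len=hap.length)
        reads.extend(generate_reads(frags, hap, cfg, rng, id_prefix=f"sim{hap_i}"))
    return SimulatedDataset(
        reads=reads,
        truth=truth,
        mutated=mutated,
        haplotypes=haplotypes,
        regions=regions_out,
        config=cfg,
    )
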