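"""Reading and writing of the standard formats the tool touches.

All byte-level conventions live here: FASTA references, FASTQ reads, SAM
mapping output and minimal VCF 4.2 variant output.  Internally every
coordinate is 0-based half-open; the 1-based inclusive SAM/VCF convention is
applied only at the boundary of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ConsistencyError, FormatError

__all__ = [
    "ReferenceSeq",
    "Read",
    "Variant",
    "SamRecord",
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "write_sam",
    "read_sam",
    "write_vcf",
    "read_vcf",
]

_VALID = set("ACGTN")


def _normalize(seq: str) -> str:
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass(frozen=True)
class ReferenceSeq:
    """A named reference sequence over the alphabet {A,C,G,T,N}."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base PHRED qualities."""

    id: str
    bases: str
    quals: np.ndarray  # int PHRED scores, same length as bases

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )
        if len(self.bases) < 1:
            raise FormatError(f"read {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Variant:
    """A sequence variant in 0-based internal coordinates.

    SNP: ``pos`` is the substituted site, ``ref``/``alt`` are single bases.
    DEL: ``pos`` is the first deleted base, ``ref`` the deleted run, ``alt`` "".
    INS: ``pos`` is the base the insertion follows, ``ref`` "", ``alt`` the
    inserted sequence.  VCF left-anchoring is applied only on write.
    """

    chrom: str
    pos: int
    type: str  # "SNP" | "INS" | "DEL"
    ref: str
    alt: str
    score: float = 0.0
    depth: int = 0
    zygosity: str = "hom"

    @property
    def length(self) -> int:
        return len(self.ref) if self.type == "DEL" else len(self.alt)


@dataclass
class SamRecord:
    """A parsed SAM alignment, attribute-compatible with mapper.Alignment."""

    read_id: str
    ref_name: str | None
    strand: str
    ref_start: int  # 0-based
    cigar: list[tuple[str, int]]
    bases: str
    quals: np.ndarray
    mapped: bool
    mapq: int = 0


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[ReferenceSeq]:
    """Load FASTA records in file order, normalizing to uppercase ACGTN."""
    with open(path) as fh:
        first = None
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file (line {lineno or 1})")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header starting with '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ReferenceSeq(rec.id, _normalize(str(rec.seq))))
    if not records:
        raise FormatError(f"{path}: no FASTA records found (line 1)")
    return records


def read_fastq(path, phred_offset: int = 33) -> list[Read]:
    """Load FASTQ reads; qualities decoded as ASCII minus ``phred_offset``."""
    if phred_offset not in (33, 64):
        raise FormatError(f"unsupported PHRED offset {phred_offset}")
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    reads = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16)
            reads.append(Read(rec.id, _normalize(str(rec.seq)), quals))
    except ValueError as exc:  # Biopython signals truncated/mismatched records
        raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path, phred_offset: int = 33) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + phred_offset) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM


def cigar_string(ops: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def write_sam(alignments, refs: Sequence[ReferenceSeq], path) -> None:
    """Write alignments as SAM 1.x with M/I/D CIGAR operations.

    ``alignments`` may be mapper.Alignment objects or SamRecord; unmapped
    records are emitted with flag 4 per SAM convention.
    """
    ref_names = {r.name for r in refs}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for r in refs:
            fh.write(f"@SQ\tSN:{r.name}\tLN:{r.length}\n")
        fh.write("@PG\tID:sap\tPN:sap\n")
        for a in alignments:
            qual = "".join(chr(int(q) + 33) for q in a.quals)
            if not a.mapped:
                fh.write(f"{a.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{a.bases}\t{qual}\n")
                continue
            if a.ref_name not in ref_names:
                raise ConsistencyError(f"alignment references unknown sequence {a.ref_name!r}")
            flag = 16 if a.strand == "-" else 0
            fh.write(
                f"{a.read_id}\t{flag}\t{a.ref_name}\t{a.ref_start + 1}\t{a.mapq}\t"
                f"{cigar_string(a.cigar)}\t*\t0\t0\t{a.bases}\t{qual}\n"
            )


_CIGAR_OPS = "MIDNSHP=X"


def read_sam(path) -> list[SamRecord]:
    """Parse a SAM file back into records (uses pysam)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            mapped = not rec.is_unmapped
            cigar = (
                [(_CIGAR_OPS[op], ln) for op, ln in rec.cigartuples] if rec.cigartuples else []
            )
            quals = (
                np.asarray(rec.query_qualities, dtype=np.int16)
                if rec.query_qualities is not None
                else np.zeros(len(rec.query_sequence or ""), dtype=np.int16)
            )
            out.append(
                SamRecord(
                    read_id=rec.query_name,
                    ref_name=rec.reference_name if mapped else None,
                    strand="-" if rec.is_reverse else "+",
                    ref_start=rec.reference_start if mapped else -1,
                    cigar=cigar,
                    bases=_normalize(rec.query_sequence or ""),
                    quals=quals,
                    mapped=mapped,
                    mapq=rec.mapping_quality,
                )
            )
    return out


# ---------------------------------------------------------------------------
# VCF


def write_vcf(calls: Iterable[Variant], refs: Sequence[ReferenceSeq], path) -> None:
    """Write a minimal VCF 4.2 with left-anchored InDels.

    Insertions and deletions are anchored on the preceding reference base
    (or the following base for an event at position 0).
    """
    seqs = {r.name: r.sequence for r in refs}
    lines = []
    for v in sorted(calls, key=lambda v: (v.chrom, v.pos, v.type)):
        if v.chrom not in seqs:
            raise ConsistencyError(f"variant references unknown sequence {v.chrom!r}")
        seq = seqs[v.chrom]
        if v.type == "SNP":
            if v.alt == v.ref:
                raise ConsistencyError(f"SNP at {v.chrom}:{v.pos + 1} has ALT == REF")
            pos1, ref, alt = v.pos + 1, v.ref, v.alt
        elif v.type == "DEL":
            if v.pos > 0:
                anchor = seq[v.pos - 1]
                pos1, ref, alt = v.pos, anchor + v.ref, anchor
            else:  # deletion at the very start: anchor on the following base
                anchor = seq[v.pos + len(v.ref)]
                pos1, ref, alt = 1, v.ref + anchor, anchor
        elif v.type == "INS":
            anchor = seq[v.pos]
            pos1, ref, alt = v.pos + 1, anchor, anchor + v.alt
        else:
            raise ConsistencyError(f"unknown variant type {v.type!r}")
        if ref == alt:
            raise ConsistencyError(f"variant at {v.chrom}:{pos1} has ALT == REF")
        info = f"TYPE={v.type};DP={v.depth};ZYG={v.zygosity}"
        lines.append(f"{v.chrom}\t{pos1}\t.\t{ref}\t{alt}\t{v.score:.4g}\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting depth">\n')
        fh.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity">\n')
        for r in refs:
            fh.write(f"##contig=<ID={r.name},length={r.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_vcf(path) -> list[Variant]:
    """Parse a VCF into internal 0-based Variant records (uses pysam)."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref, alt = rec.ref, rec.alts[0] if rec.alts else ""
            info = dict(rec.info)
            depth = int(info.get("DP", 0))
            zyg = str(info.get("ZYG", "hom"))
            score = float(rec.qual) if rec.qual is not None else 0.0
            if len(ref) == 1 and len(alt) == 1:
                out.append(Variant(rec.chrom, rec.start, "SNP", ref, alt, score, depth, zyg))
            elif len(ref) > len(alt):
                if ref.startswith(alt):  # left-anchored deletion
                    out.append(
                        Variant(rec.chrom, rec.start + len(alt), "DEL", ref[len(alt):], "",
                                score, depth, zyg)
                    )
                else:  # right-anchored (event at position 0)
                    out.append(Variant(rec.chrom, rec.start, "DEL", ref[: len(ref) - len(alt)],
                                       "", score, depth, zyg))
            elif len(alt) > len(ref):
                if alt.startswith(ref):
                    out.append(
                        Variant(rec.chrom, rec.start + len(ref) - 1, "INS", "", alt[len(ref):],
                                score, depth, zyg)
                    )
                else:
                    out.append(Variant(rec.chrom, rec.start, "INS", "", alt[: len(alt) - len(ref)],
                                       score, depth, zyg))
            else:
                raise FormatError(f"{path}: unsupported allele pair {ref}>{alt}")
    return out
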