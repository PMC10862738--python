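"""Readers and writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open. The only 1-based surface is
VCF, and conversion happens at the read/write boundary of this module.

Formats handled:

* reference FASTA (one record per chromosome),
* VCF v4.2 with per-sample ``AD``/``DP`` fields (single-base substitutions
  only; indels, MNVs and symbolic alleles are skipped and counted),
* copy-number segment tables (CNVkit ``call.cns``-like TSV with integer
  total copy number),
* chromosome-arm boundary tables (BED-like TSV).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "VariantRecord",
    "SegmentRecord",
    "ArmTable",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_segments",
    "write_segments",
    "read_arm_table",
    "write_arm_table",
]

_VALID_BASES = frozenset("ACGTN")
_SBS_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file violated the format contract (bad character, overlap, ...)."""


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome of the reference genome, uppercase over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"sequence {self.name!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """A single-base substitution with allele depths for one sample.

    ``pos`` is the 0-based genomic index of the substituted base.  The
    1-based VCF POS is ``pos + 1``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    alt_depth: int
    total_depth: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in _SBS_BASES or self.alt not in _SBS_BASES:
            raise ValueError(
                f"non-SBS alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, {self.total_depth}]"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction: alt reads over total reads at the site."""
        if self.total_depth == 0:
            return 0.0
        return self.alt_depth / self.total_depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the substitution, independent of sample and depths."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SegmentRecord:
    """A total-copy-number segment for one sample (0-based half-open)."""

    chrom: str
    start: int
    end: int
    total_cn: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.total_cn < 0:
            raise ValueError(f"negative copy number {self.total_cn}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class ArmEntry:
    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int


@dataclass
class ArmTable:
    """Chromosome-arm boundaries; arms of one chromosome are disjoint."""

    entries: list[ArmEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[ArmEntry]] = {}
        for e in self.entries:
            by_chrom.setdefault(e.chrom, []).append(e)
        for chrom, arms in by_chrom.items():
            arms = sorted(arms, key=lambda a: a.start)
            for a, b in zip(arms, arms[1:]):
                if a.end > b.start:
                    raise FormatError(
                        f"overlapping arms on {chrom}: "
                        f"{a.arm}[{a.start},{a.end}) and {b.arm}[{b.start},{b.end})"
                    )

    def assign(self, chrom: str, pos: int) -> tuple[str, str] | None:
        """Return (chrom, arm) containing ``pos``, or None if unassigned."""
        for e in self.entries:
            if e.chrom == chrom and e.start <= pos < e.end:
                return (e.chrom, e.arm)
        return None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records.

    Lowercase is normalized to uppercase; any character outside {A,C,G,T,N}
    raises :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    out: list[GenomeSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has illegal characters {sorted(bad)}"
            )
        out.append(GenomeSequence(name=rec.id, sequence=seq))
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Iterable[GenomeSequence], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | os.PathLike, sample: str) -> tuple[list[VariantRecord], int]:
    """Read biallelic SBS records for one sample from a VCF.

    Multiallelic records are split into per-alt records; the per-alt VAF is
    the alt's AD over the summed AD of all alleles. Indels and symbolic
    alleles are skipped. Returns ``(records, n_skipped)``.

    Raises KeyError for a missing sample and FormatError when neither AD nor
    DP + alt count is available.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        if sample not in vcf.header.samples:
            raise KeyError(
                f"{path}: sample {sample!r} not in VCF "
                f"(has {list(vcf.header.samples)})"
            )
        for rec in vcf:
            ref = rec.ref.upper() if rec.ref else ""
            alts = rec.alts or ()
            call = rec.samples[sample]
            ad = call.get("AD")
            if ad is None or all(a is None for a in ad):
                dp = call.get("DP")
                if dp is None:
                    raise FormatError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks AD and DP "
                        f"for sample {sample!r}"
                    )
                # Without AD we cannot apportion alt reads; treat as field error
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks AD for sample "
                    f"{sample!r}; allele depths are required"
                )
            total = sum(int(a) for a in ad if a is not None)
            for i, alt in enumerate(alts):
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in _SBS_BASES \
                        or alt not in _SBS_BASES:
                    skipped += 1
                    continue
                alt_depth = int(ad[i + 1]) if ad[i + 1] is not None else 0
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,  # VCF is 1-based
                        ref=ref,
                        alt=alt,
                        sample_id=sample,
                        alt_depth=alt_depth,
                        total_depth=total,
                    )
                )
    return records, skipped


def write_vcf(records: Sequence[VariantRecord], path: str | os.PathLike,
              sample: str, contigs: Sequence[tuple[str, int]] | None = None) -> None:
    """Write SBS records as a minimal single-sample VCF v4.2 with GT:AD:DP.

    Output is deterministic: records are written in (chrom, pos, alt) order
    and no timestamp is embedded, so identical inputs yield identical bytes.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        ref_depth = r.total_depth - r.alt_depth
        gt = "1/1" if r.vaf > 0.9 else ("0/1" if r.alt_depth > 0 else "0/0")
        lines.append(
            f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
            f"GT:AD:DP\t{gt}:{ref_depth},{r.alt_depth}:{r.total_depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Segment tables


def read_segments(path: str | os.PathLike, sample: str | None = None
                  ) -> list[SegmentRecord]:
    """Read a copy-number segment TSV (``chrom  start  end  cn`` header).

    Coordinates in the file are 0-based half-open (CNVkit convention).
    When ``sample`` is None the sample id is the file-name stem, matching
    the one-file-per-sample convention. Overlapping segments raise.
    """
    path = Path(path)
    sample_id = sample if sample is not None else path.stem.removesuffix(".call")
    segs: list[SegmentRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for want in ("chrom", "start", "end", "cn"):
            if want not in cols:
                raise FormatError(f"{path}: missing column {want!r} in header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            cn_text = parts[cols["cn"]]
            try:
                cn = int(cn_text)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer copy number {cn_text!r}"
                ) from None
            if cn < 0:
                raise FormatError(f"{path}:{lineno}: negative copy number {cn}")
            segs.append(
                SegmentRecord(
                    chrom=parts[cols["chrom"]],
                    start=int(parts[cols["start"]]),
                    end=int(parts[cols["end"]]),
                    total_cn=cn,
                    sample_id=sample_id,
                )
            )
    _check_no_overlap(segs, str(path))
    return segs


def _check_no_overlap(segs: Sequence[SegmentRecord], where: str) -> None:
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if a.end > b.start:
                raise FormatError(
                    f"{where}: overlapping segments on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def write_segments(segs: Sequence[SegmentRecord], path: str | os.PathLike) -> None:
    lines = ["chrom\tstart\tend\tcn"]
    for s in sorted(segs, key=lambda s: (s.chrom, s.start)):
        lines.append(f"{s.chrom}\t{s.start}\t{s.end}\t{s.total_cn}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Arm tables


def read_arm_table(path: str | os.PathLike) -> ArmTable:
    """Read a BED-like arm table: ``chrom  start  end  arm`` (0-based half-open)."""
    entries: list[ArmEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "chrom\t")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            entries.append(
                ArmEntry(chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                         arm=parts[3])
            )
    return ArmTable(entries=entries)


def write_arm_table(arms: ArmTable, path: str | os.PathLike) -> None:
    lines = [
        f"{e.chrom}\t{e.start}\t{e.end}\t{e.arm}"
        for e in sorted(arms.entries, key=lambda e: (e.chrom, e.start))
    ]
    Path(path).write_text("\n".join(lines) + "\n")
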