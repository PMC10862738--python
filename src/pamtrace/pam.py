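"""Somatic PAM-site discovery.

A single-base substitution creates a novel SpCas9 PAM when the mutant base
turns a dinucleotide overlapping the mutated position into ``GG`` on the
plus strand, or into ``CC`` on the forward sequence (which reads ``GG`` on
the minus strand). The ``N`` of the NGG motif is irrelevant to novelty:
mutating the N cannot create a PAM where the GG already existed.

One substitution can create at most two PAMs — both flanking dinucleotides
can gain GG (alt G between two G neighbours) or CC (alt C between two C
neighbours); an alt outside {G, C} can never create one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import GenomeSequence, VariantRecord

__all__ = [
    "GermlineFilter",
    "PamCreation",
    "SomaticPamSet",
    "subtract_somatic",
    "detect_novel_pams",
    "filter_high_vaf",
    "pam_creation_rate",
    "PROTOSPACER_LENGTH",
]

PROTOSPACER_LENGTH = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GermlineFilter:
    """Quality gates applied to germline variants before subtraction.

    Germline calls failing these gates are unreliable and are not used to
    subtract (they cannot rescue a tumor variant as "somatic").
    """

    min_mapping_quality: float = 20.0
    min_depth: int = 10
    min_allele_frequency: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_mapping_quality, self.min_depth,
               self.min_allele_frequency) < 0:
            raise ValueError("germline filter thresholds must be non-negative")

    def passes(self, v: VariantRecord, mapping_quality: float | None = None) -> bool:
        if mapping_quality is not None and mapping_quality < self.min_mapping_quality:
            return False
        return (v.total_depth >= self.min_depth
                and v.vaf >= self.min_allele_frequency)


@dataclass(frozen=True)
class PamCreation:
    """A somatic SBS annotated with one novel PAM it creates.

    ``pam_start`` is the 0-based genomic start of the 3-base window: the
    NGG window for a plus-strand PAM, the CCN window (forward coordinates)
    for a minus-strand PAM. ``gg_positions`` are the forward-strand
    coordinates of the novel GG (plus) or CC (minus) dinucleotide.
    ``protospacer`` is read 5'→3' on the PAM strand from the mutant
    sequence; near a contig end it may be shorter than 20 bases, in which
    case ``truncated_protospacer`` is set.
    """

    variant: VariantRecord
    pam_start: int
    strand: str  # "+" or "-"
    gg_positions: tuple[int, int]
    protospacer: str
    truncated_protospacer: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.variant.pos not in self.gg_positions:
            raise ValueError("mutated position must lie within gg_positions")


@dataclass
class SomaticPamSet:
    """All PAM creations for one tumor sample of a case."""

    case_id: str
    sample_id: str
    pams: list[PamCreation] = field(default_factory=list)
    high_vaf_threshold: float | None = None

    @property
    def high_vaf_subset(self) -> list[PamCreation]:
        if self.high_vaf_threshold is None:
            return list(self.pams)
        return [p for p in self.pams if p.variant.vaf >= self.high_vaf_threshold]


class ReferenceMismatchError(ValueError):
    """The variant's declared ref allele disagrees with the reference sequence."""


def subtract_somatic(
    tumor: Iterable[VariantRecord],
    normal: Iterable[VariantRecord],
    germline_filter: GermlineFilter | None = None,
    normal_mapping_quality: dict[tuple, float] | None = None,
) -> list[VariantRecord]:
    """Remove germline variants from the tumor set by exact-key subtraction.

    A tumor variant is somatic when its (chrom, pos, ref, alt) key is absent
    from the quality-filtered normal set. Normal variants failing the
    germline filter are dropped *before* subtraction — a low-quality
    germline call does not make a tumor variant germline, but neither can it
    be trusted, so it simply does not participate.

    ``normal_mapping_quality`` optionally maps variant keys to MQ values for
    the mapping-quality gate (depth and allele-frequency gates come from the
    records themselves).
    """
    tumor = list(tumor)
    if not tumor:
        warnings.warn("empty tumor variant collection; somatic set is empty",
                      stacklevel=2)
        return []
    gf = germline_filter or GermlineFilter()
    normal_keys = set()
    for v in normal:
        mq = None
        if normal_mapping_quality is not None:
            mq = normal_mapping_quality.get(v.key)
        if gf.passes(v, mapping_quality=mq):
            normal_keys.add(v.key)
    return [v for v in tumor if v.key not in normal_keys]


def detect_novel_pams(
    variant: VariantRecord,
    reference: GenomeSequence,
    protospacer_length: int = PROTOSPACER_LENGTH,
) -> list[PamCreation]:
    """Find the novel NGG PAMs created by one substitution.

    Checks the two dinucleotides overlapping the mutated base. A plus-strand
    creation is a dinucleotide that is GG in the mutant but was not GG in
    the germline; a minus-strand creation is the same for CC (GG on the
    reverse strand). Dinucleotides containing N in the germline are skipped.

    Raises :class:`ReferenceMismatchError` when the reference base at the
    variant position differs from ``variant.ref``.
    """
    seq = reference.sequence
    pos = variant.pos
    if not 0 <= pos < len(seq):
        raise ReferenceMismatchError(
            f"position {pos} outside {reference.name} (length {len(seq)})"
        )
    if seq[pos] != variant.ref:
        raise ReferenceMismatchError(
            f"reference {reference.name}:{pos} is {seq[pos]}, "
            f"variant declares ref {variant.ref}"
        )

    out: list[PamCreation] = []
    # Dinucleotide windows overlapping the mutated base: (pos-1,pos), (pos,pos+1)
    for start in (pos - 1, pos):
        end = start + 2
        if start < 0 or end > len(seq):
            continue
        germ = seq[start:end]
        if "N" in germ:
            continue
        mut = "".join(
            variant.alt if i == pos else seq[i] for i in range(start, end)
        )
        if mut == "GG" and germ != "GG" and start - 1 >= 0:
            # Plus strand: PAM window N-G-G starts one base left of the GG.
            pam_start = start - 1
            proto, truncated = _extract_protospacer(
                seq, variant, pam_start - protospacer_length, pam_start, "+",
                protospacer_length,
            )
            out.append(
                PamCreation(variant=variant, pam_start=pam_start, strand="+",
                            gg_positions=(start, start + 1), protospacer=proto,
                            truncated_protospacer=truncated)
            )
        if mut == "CC" and germ != "CC" and end < len(seq):
            # Minus strand: forward CCN window starts at the first C; the
            # protospacer lies 3' of the window in forward coordinates.
            pam_start = start
            proto_fwd_start = end + 1
            proto, truncated = _extract_protospacer(
                seq, variant, proto_fwd_start,
                proto_fwd_start + protospacer_length, "-", protospacer_length,
            )
            out.append(
                PamCreation(variant=variant, pam_start=pam_start, strand="-",
                            gg_positions=(start, start + 1), protospacer=proto,
                            truncated_protospacer=truncated)
            )
    return out


def _extract_protospacer(
    seq: str, variant: VariantRecord, start: int, end: int, strand: str,
    wanted: int,
) -> tuple[str, bool]:
    lo, hi = max(start, 0), min(end, len(seq))
    if lo >= hi:
        return "", True
    window = "".join(
        variant.alt if i == variant.pos else seq[i] for i in range(lo, hi)
    )
    if strand == "-":
        window = reverse_complement(window)
    return window, len(window) < wanted


def filter_high_vaf(pams: SomaticPamSet, threshold: float = 0.95) -> SomaticPamSet:
    """Subset a PAM set to creations whose VAF is >= threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    kept = [p for p in pams.pams if p.variant.vaf >= threshold]
    return SomaticPamSet(case_id=pams.case_id, sample_id=pams.sample_id,
                         pams=kept, high_vaf_threshold=threshold)


def pam_creation_rate(
    variants: Sequence[VariantRecord], reference: GenomeSequence
) -> float:
    """Fraction of substitutions that create at least one novel PAM.

    Counts variants with one or more creations over all variants — not
    creations per variant, so a double creator still counts once.
    """
    if not variants:
        raise ValueError("cannot compute a creation rate on zero variants")
    n_creating = sum(
        1 for v in variants if detect_novel_pams(v, reference)
    )
    return n_creating / len(variants)
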