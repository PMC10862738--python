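"""VAF–copy-number modelling and loss-of-heterozygosity classification.

The expected VAF of a somatic mutation carried on ``m`` of ``C_T`` tumor
copies, in a sample of purity ``p`` whose contaminating normal cells carry
``C_N`` copies (2 for autosomes), is

    E[VAF] = p * m / (p * C_T + (1 - p) * C_N)

At purity 1 a heterozygous diploid site sits at 0.5, a haploid (copy-loss
LOH) or copy-neutral LOH site at 1.0, and a triploid site at 1/3 or 2/3
depending on multiplicity. Segments are called LOH when nearly all
informative somatic variants sit at the VAF expected for m = C_T;
cross-sample agreement then splits regions into truncal LOH (every sample),
private LOH (some samples), or retained heterozygosity (none).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ArmTable, SegmentRecord, VariantRecord

__all__ = [
    "ExpectedVafModel",
    "expected_vaf",
    "ZygosityCall",
    "ZygosityParams",
    "classify_segment_zygosity",
    "LohScope",
    "classify_loh_scope",
    "region_grid",
    "per_arm_summary",
]


@dataclass(frozen=True)
class ExpectedVafModel:
    """Purity / copy-number / multiplicity model for one locus."""

    purity: float
    tumor_total_cn: int
    multiplicity: int
    normal_cn: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.tumor_total_cn < 0:
            raise ValueError("tumor total CN must be non-negative")
        if not 0 <= self.multiplicity <= self.tumor_total_cn:
            raise ValueError(
                f"multiplicity {self.multiplicity} outside "
                f"[0, {self.tumor_total_cn}]"
            )


def expected_vaf(
    purity: float, tumor_total_cn: int, multiplicity: int, normal_cn: int = 2
) -> float:
    """Expected variant allele fraction p·m / (p·C_T + (1−p)·C_N)."""
    model = ExpectedVafModel(purity, tumor_total_cn, multiplicity, normal_cn)
    denom = model.purity * model.tumor_total_cn \
        + (1 - model.purity) * model.normal_cn
    if denom <= 0:
        raise ZeroDivisionError(
            "degenerate sample: no DNA copies at the locus "
            f"(p={purity}, C_T={tumor_total_cn}, C_N={normal_cn})"
        )
    return model.purity * model.multiplicity / denom


@dataclass(frozen=True)
class ZygosityParams:
    """Thresholds for per-segment zygosity calling.

    A segment with total CN 1 is hemizygous by definition and is called LOH
    from the copy number alone. At CN >= 2 the segment is LOH when at least
    ``loh_fraction`` of informative variants sit at or above the LOH VAF
    threshold: at purity 1 that threshold is ``high_vaf_cut``; at lower
    purity it is the expected m = C_T VAF minus a depth-aware tolerance
    (0.1 absolute at depth >= 30, else 3 binomial standard deviations).

    ``loh_fraction`` defaults to 0.6: a truly heterozygous diploid region
    at purity 1 and practical depth puts essentially no variants at the
    peak, while a copy-neutral LOH region legitimately mixes a dominant
    peak cluster (pre-LOH mutations, duplicated) with post-LOH passengers
    at half the peak — demanding near-unanimity would misread those
    regions as heterozygous.
    """

    high_vaf_cut: float = 0.95
    loh_fraction: float = 0.6
    min_support: int = 3
    base_tolerance: float = 0.1
    tolerance_depth: int = 30


def vaf_tolerance(expected: float, depth: int, params: ZygosityParams) -> float:
    """Absolute tolerance around an expected VAF peak at a given depth."""
    if depth >= params.tolerance_depth:
        return params.base_tolerance
    if depth <= 0:
        return 1.0
    return 3.0 * math.sqrt(expected * (1 - expected) / depth)


@dataclass(frozen=True)
class ZygosityCall:
    """Per-sample zygosity of one segment."""

    segment: SegmentRecord
    state: str  # heterozygous | loh | indeterminate
    loh_mode: str  # copy_loss | copy_neutral | not_applicable
    support: int

    def __post_init__(self) -> None:
        if self.state not in ("heterozygous", "loh", "indeterminate"):
            raise ValueError(f"bad state {self.state!r}")
        if self.loh_mode == "copy_loss" and self.segment.total_cn > 1:
            raise ValueError("copy_loss requires total CN <= 1")
        if self.loh_mode == "copy_neutral" and self.segment.total_cn < 2:
            raise ValueError("copy_neutral requires total CN >= 2")


def classify_segment_zygosity(
    segment: SegmentRecord,
    variants: Iterable[VariantRecord],
    purity: float = 1.0,
    params: ZygosityParams | None = None,
) -> ZygosityCall:
    """Call a segment heterozygous / LOH / indeterminate from somatic VAFs.

    Only variants inside the segment are informative. With fewer than
    ``min_support`` informative variants the call is indeterminate. A CN 1
    segment is LOH (copy_loss) from the copy number alone; a CN >= 2
    segment is LOH (copy_neutral) when the fraction of informative variants
    at the m = C_T VAF peak reaches ``loh_fraction``.
    """
    params = params or ZygosityParams()
    inside = [v for v in variants if v.chrom == segment.chrom
              and segment.contains(v.pos)]
    support = len(inside)
    if support < params.min_support:
        return ZygosityCall(segment=segment, state="indeterminate",
                            loh_mode="not_applicable", support=support)
    cn = segment.total_cn
    if cn == 0:
        # No tumor copies: any reads are contamination; nothing to call.
        return ZygosityCall(segment=segment, state="indeterminate",
                            loh_mode="not_applicable", support=support)
    if cn == 1:
        # A single surviving copy is hemizygous by definition.
        return ZygosityCall(segment=segment, state="loh",
                            loh_mode="copy_loss", support=support)

    if purity >= 1.0:
        threshold = params.high_vaf_cut
    else:
        exp_loh = expected_vaf(purity, cn, cn)
        mean_depth = int(np.mean([v.total_depth for v in inside]))
        threshold = exp_loh - vaf_tolerance(exp_loh, mean_depth, params)
    frac_at_peak = sum(v.vaf >= threshold for v in inside) / support
    if frac_at_peak >= params.loh_fraction:
        return ZygosityCall(segment=segment, state="loh",
                            loh_mode="copy_neutral", support=support)
    return ZygosityCall(segment=segment, state="heterozygous",
                        loh_mode="not_applicable", support=support)


@dataclass(frozen=True)
class LohScope:
    """Cross-sample classification of one region.

    ``truncal_loh``: every determinate sample is LOH (occurred before
    lineage divergence); ``private_loh``: at least one but not all;
    ``retained_het``: none. Regions where all samples are LOH but the modes
    disagree stay ``truncal_loh`` for maintenance purposes with
    ``mixed_mode`` set.
    """

    chrom: str
    start: int
    end: int
    scope: str
    samples_loh: tuple[str, ...]
    samples_total: int
    mixed_mode: bool = False

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def classify_loh_scope(
    region: tuple[str, int, int],
    calls: Mapping[str, ZygosityCall],
) -> LohScope:
    """Combine per-sample zygosity calls for one region into an LOH scope.

    Indeterminate calls are excluded from the denominator; a region where
    every call is indeterminate raises.
    """
    determinate = {s: c for s, c in calls.items() if c.state != "indeterminate"}
    if not determinate:
        raise ValueError(
            f"all zygosity calls indeterminate for region {region}; "
            "cannot assign an LOH scope"
        )
    loh_samples = tuple(sorted(s for s, c in determinate.items()
                               if c.state == "loh"))
    n_loh, n_total = len(loh_samples), len(determinate)
    mixed = False
    if n_loh == n_total:
        modes = {determinate[s].loh_mode for s in loh_samples}
        mixed = len(modes) > 1
        scope = "truncal_loh"
    elif n_loh == 0:
        scope = "retained_het"
    else:
        scope = "private_loh"
    chrom, start, end = region
    return LohScope(chrom=chrom, start=start, end=end, scope=scope,
                    samples_loh=loh_samples, samples_total=n_total,
                    mixed_mode=mixed)


def region_grid(
    segments_by_sample: Mapping[str, Sequence[SegmentRecord]]
) -> list[tuple[str, int, int]]:
    """Union of segment breakpoints across samples → shared region grid.

    Every returned region lies inside exactly one segment of every sample,
    so per-sample zygosity calls are well defined on it.
    """
    by_chrom: dict[str, set[int]] = {}
    for segs in segments_by_sample.values():
        for s in segs:
            by_chrom.setdefault(s.chrom, set()).update((s.start, s.end))
    regions: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        points = sorted(by_chrom[chrom])
        regions.extend(
            (chrom, a, b) for a, b in zip(points, points[1:])
        )
    return regions


def per_arm_summary(
    sample_id: str,
    truncal_pam_positions: Sequence[tuple[str, int]],
    variants_by_key: Mapping[tuple[str, int], VariantRecord],
    segments: Sequence[SegmentRecord],
    arms: ArmTable,
    present: Mapping[tuple[str, int], bool],
) -> pd.DataFrame:
    """Per chromosome arm: mean truncal-PAM VAF, length-weighted mean CN,
    and the fraction of truncal PAMs present in the sample.

    ``variants_by_key`` maps (chrom, pos) to the sample's variant record at
    that site (absent sites contribute VAF 0); ``present`` maps the same
    keys to the presence call. PAMs outside any arm go to an "unassigned"
    bucket with a warning.
    """
    rows: dict[tuple[str, str], dict] = {}

    def bucket(key: tuple[str, str]) -> dict:
        return rows.setdefault(
            key, {"vafs": [], "n_pams": 0, "n_present": 0}
        )

    for chrom, pos in truncal_pam_positions:
        assigned = arms.assign(chrom, pos)
        if assigned is None:
            warnings.warn(f"PAM at {chrom}:{pos} outside every arm",
                          stacklevel=2)
            assigned = (chrom, "unassigned")
        b = bucket(assigned)
        b["n_pams"] += 1
        v = variants_by_key.get((chrom, pos))
        b["vafs"].append(v.vaf if v is not None else 0.0)
        if present.get((chrom, pos), False):
            b["n_present"] += 1

    # Length-weighted mean CN per arm from the sample's segments.
    cn_weight: dict[tuple[str, str], list[float]] = {}
    for seg in segments:
        for entry in arms.entries:
            if entry.chrom != seg.chrom:
                continue
            lo, hi = max(seg.start, entry.start), min(seg.end, entry.end)
            if lo < hi:
                cn_weight.setdefault((entry.chrom, entry.arm), []).append(
                    seg.total_cn * (hi - lo)
                )
                cn_weight.setdefault((entry.chrom, entry.arm) + ("len",), []
                                     ).append(hi - lo)  # type: ignore[arg-type]

    # Arms covered by segments but holding no truncal PAM still get a row
    # (maintenance missing) so the table enumerates the genome analysed.
    for key in list(cn_weight):
        if len(key) == 2:
            bucket(key)  # type: ignore[arg-type]

    records = []
    for (chrom, arm), b in sorted(rows.items()):
        weights = cn_weight.get((chrom, arm), [])
        lengths = cn_weight.get((chrom, arm, "len"), [])
        mean_cn = sum(weights) / sum(lengths) if lengths else float("nan")
        records.append({
            "chrom": chrom,
            "arm": arm,
            "sample_id": sample_id,
            "n_truncal_pams": b["n_pams"],
            "mean_vaf": float(np.mean(b["vafs"])) if b["vafs"] else float("nan"),
            "mean_cn": mean_cn,
            "maintenance": (b["n_present"] / b["n_pams"]
                            if b["n_pams"] else float("nan")),
        })
    return pd.DataFrame.from_records(
        records,
        columns=["chrom", "arm", "sample_id", "n_truncal_pams", "mean_vaf",
                 "mean_cn", "maintenance"],
    )
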