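"""End-to-end case pipeline: discover → classify → maintain → report.

A case manifest (YAML) lists the reference, the matched-normal VCF, one VCF
and one copy-number segment table per tumor sample (with a primary or
metastasis role and a purity), and the arm table. The pipeline

1. subtracts normal from each tumor variant set and detects novel-PAM
   creating substitutions,
2. builds the PAM × sample presence matrix from capture-style depths,
3. defines the truncal PAM set (union over primaries; inferred from
   metastases when no primary exists),
4. applies the depth/percent-truncal QC to exclude low-cellularity samples,
5. calls per-segment zygosity, classifies regions into truncal/private LOH
   or retained heterozygosity, and
6. computes maintenance statistics overall, by LOH class and by arm.

Every number in the report is recomputed from the stage outputs; reruns
with the same manifest and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (ArmTable, GenomeSequence, SegmentRecord, VariantRecord,
                 read_arm_table, read_fasta, read_segments, read_vcf)
from .loh import (LohScope, ZygosityParams, classify_loh_scope,
                  classify_segment_zygosity, per_arm_summary, region_grid)
from .maintenance import (PresenceMatrix, TruncalSet, call_presence,
                          define_truncal_union, group_tests,
                          infer_truncal_from_mets, maintenance_by_loh_class,
                          percent_maintained, percent_truncal, qc_depth_filter,
                          shared_by_all, set_overlaps)
from .pam import GermlineFilter, detect_novel_pams, subtract_somatic

__all__ = ["PipelineParams", "CaseManifest", "CaseReport", "run_pipeline"]

log = logging.getLogger("pamtrace")


@dataclass(frozen=True)
class PipelineParams:
    vaf_cut: float = 0.05
    min_depth_presence: int = 20
    high_vaf: float = 0.95
    qc_min_depth: float = 30.0
    min_mets_for_truncal: int = 2
    germline: GermlineFilter = field(default_factory=GermlineFilter)
    zygosity: ZygosityParams = field(default_factory=ZygosityParams)


@dataclass
class SampleInput:
    sample_id: str
    role: str  # primary | metastasis
    vcf: Path
    segments: Path
    purity: float = 1.0


@dataclass
class CaseManifest:
    case_id: str
    reference: Path
    arms: Path
    normal_vcf: Path
    normal_sample: str
    samples: list[SampleInput]
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CaseManifest":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        samples = [
            SampleInput(sample_id=s["sample_id"], role=s["role"],
                        vcf=resolve(s["vcf"]), segments=resolve(s["segments"]),
                        purity=float(s.get("purity", 1.0)))
            for s in raw["samples"]
        ]
        params_raw = raw.get("params", {}) or {}
        params = PipelineParams(**params_raw)
        manifest = cls(
            case_id=raw["case_id"],
            reference=resolve(raw["reference"]),
            arms=resolve(raw["arms"]),
            normal_vcf=resolve(raw["normal_vcf"]),
            normal_sample=raw.get("normal_sample", "normal"),
            samples=samples,
            params=params,
            seed=int(raw.get("seed", 0)),
        )
        manifest.validate()
        return manifest

    def validate(self) -> None:
        missing = [str(p) for p in
                   [self.reference, self.arms, self.normal_vcf]
                   + [s.vcf for s in self.samples]
                   + [s.segments for s in self.samples]
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(
                "manifest references missing files: " + ", ".join(missing)
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("manifest lists duplicate sample ids")
        if not self.samples:
            raise ValueError("manifest lists no tumor samples")


@dataclass
class CaseReport:
    case_id: str
    qc: dict[str, dict[str, Any]]
    truncal_size: int
    truncal_provenance: str
    percent_truncal: dict[str, float | None]
    percent_maintained_mean: float | None
    shared_all: float | None
    by_loh_class: pd.DataFrame
    loh_scopes: list[LohScope]
    per_arm: pd.DataFrame
    overlaps: dict[str, int]
    tests: dict[str, Any]
    provenance: dict[str, Any]

    def to_json_dict(self) -> dict:
        by_class = {
            row["loh_class"]: {
                "n_pams": int(row["n_pams"]),
                "mean_percent_maintained": (
                    None if pd.isna(row["mean_percent_maintained"])
                    else float(row["mean_percent_maintained"])),
            }
            for _, row in self.by_loh_class.iterrows()
        }
        return {
            "case_id": self.case_id,
            "qc": self.qc,
            "truncal_set": {"size": self.truncal_size,
                            "provenance": self.truncal_provenance},
            "percent_truncal": self.percent_truncal,
            "mean_percent_truncal": _mean_or_none(self.percent_truncal),
            "mean_percent_maintained": self.percent_maintained_mean,
            "shared_all": self.shared_all,
            "maintenance_by_loh_class": by_class,
            "overlaps": self.overlaps,
            "tests": self.tests,
            "provenance": self.provenance,
        }

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_path = outdir / "report.json"
        report_path.write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True,
                       allow_nan=False, default=_json_default) + "\n")
        scope_rows = [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "scope": s.scope, "samples_loh": ",".join(s.samples_loh),
             "samples_total": s.samples_total, "mixed_mode": s.mixed_mode}
            for s in self.loh_scopes
        ]
        pd.DataFrame(scope_rows).to_csv(outdir / "loh_scopes.tsv", sep="\t",
                                        index=False)
        self.per_arm.to_csv(outdir / "per_arm.tsv", sep="\t", index=False)
        self.by_loh_class.to_csv(outdir / "maintenance_by_class.tsv",
                                 sep="\t", index=False)
        return report_path


def _json_default(o):  # np scalars leak into dicts
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _mean_or_none(values: dict[str, float | None]) -> float | None:
    xs = [v for v in values.values() if v is not None]
    return float(np.mean(xs)) if xs else None


def _pam_id(v: VariantRecord) -> str:
    return f"{v.chrom}:{v.pos + 1}:{v.ref}>{v.alt}"


def run_pipeline(manifest: CaseManifest) -> CaseReport:
    """Execute the full case pipeline and return the report."""
    t0 = time.time()
    params = manifest.params
    reference = {s.name: s for s in read_fasta(manifest.reference)}
    arms = read_arm_table(manifest.arms)
    normal_records, _ = read_vcf(manifest.normal_vcf, manifest.normal_sample)
    log.info("loaded reference (%d contigs) and %d normal variants",
             len(reference), len(normal_records))

    # --- stage 1: discovery -------------------------------------------------
    records_by_sample: dict[str, list[VariantRecord]] = {}
    somatic_by_sample: dict[str, list[VariantRecord]] = {}
    pam_variants: dict[str, VariantRecord] = {}  # pam_id → exemplar variant
    creations_per_pam: dict[str, int] = {}
    for s in manifest.samples:
        records, skipped = read_vcf(s.vcf, s.sample_id)
        records_by_sample[s.sample_id] = records
        observed = [r for r in records
                    if r.total_depth > 0 and r.vaf >= params.vaf_cut]
        somatic = subtract_somatic(observed, normal_records,
                                   germline_filter=params.germline) \
            if observed else []
        somatic_by_sample[s.sample_id] = somatic
        n_creating = 0
        for v in somatic:
            creations = detect_novel_pams(v, reference[v.chrom])
            if creations:
                n_creating += 1
                pid = _pam_id(v)
                pam_variants.setdefault(pid, v)
                creations_per_pam[pid] = len(creations)
        log.info("%s: %d records (%d skipped), %d somatic, %d PAM-creating",
                 s.sample_id, len(records), skipped, len(somatic), n_creating)

    pam_ids = sorted(pam_variants)
    sample_ids = [s.sample_id for s in manifest.samples]
    if not pam_ids:
        raise ValueError(f"case {manifest.case_id}: no PAM-creating somatic "
                         "variants discovered in any sample")

    # --- stage 2: presence matrix -------------------------------------------
    depths: dict[tuple[str, str], tuple[int, int]] = {}
    for sid in sample_ids:
        by_key = {_pam_id(r): r for r in records_by_sample[sid]}
        for pid in pam_ids:
            r = by_key.get(pid)
            if r is not None:
                depths[(pid, sid)] = (r.alt_depth, r.total_depth)
    presence = PresenceMatrix.from_depths(
        depths, pam_ids, sample_ids,
        vaf_cut=params.vaf_cut, min_depth=params.min_depth_presence)

    # --- stage 3: truncal set -----------------------------------------------
    # The capture panel derives from metastasis WGS, so the candidate set for
    # truncal status is the PAMs discovered in at least one metastasis; PAMs
    # private to a primary section are not on the panel and cannot be scored.
    primary_ids = [s.sample_id for s in manifest.samples if s.role == "primary"]
    met_ids = [s.sample_id for s in manifest.samples if s.role == "metastasis"]
    met_discovered = sorted({
        _pam_id(v) for sid in met_ids for v in somatic_by_sample[sid]
        if _pam_id(v) in pam_variants
    })
    if primary_ids and met_discovered:
        rows = [presence.row(p) for p in met_discovered]
        cols = [presence.column(s) for s in primary_ids]
        panel_primary = PresenceMatrix(
            met_discovered, list(primary_ids),
            presence.present[np.ix_(rows, cols)],
            presence.no_call[np.ix_(rows, cols)])
        truncal = define_truncal_union(panel_primary,
                                       case_id=manifest.case_id)
    else:
        truncal = infer_truncal_from_mets(
            presence.subset_samples(met_ids),
            min_mets=params.min_mets_for_truncal, case_id=manifest.case_id)
    log.info("truncal set: %d PAMs (%s)", len(truncal.pam_ids),
             truncal.provenance)

    # --- stage 4: sample QC -------------------------------------------------
    qc_input: dict[str, tuple[float, float]] = {}
    mean_depths: dict[str, float] = {}
    for sid in sample_ids:
        ds = [r.total_depth for r in records_by_sample[sid]]
        mean_depth = float(np.mean(ds)) if ds else 0.0
        mean_depths[sid] = mean_depth
        pt = percent_truncal(sid, presence, truncal)
        qc_input[sid] = (mean_depth, pt if pt is not None else 0.0)
    included = qc_depth_filter(qc_input, min_depth=params.qc_min_depth)
    qc = {sid: {"mean_depth": mean_depths[sid],
                "percent_truncal": qc_input[sid][1],
                "included": included[sid]}
          for sid in sample_ids}
    included_mets = [s for s in met_ids if included[s]]
    included_all = [s for s in sample_ids if included[s]]
    log.info("QC kept %d/%d samples", len(included_all), len(sample_ids))

    # --- stage 5: zygosity and LOH scope ------------------------------------
    segments_by_sample = {
        s.sample_id: read_segments(s.segments, sample=s.sample_id)
        for s in manifest.samples
    }
    purity = {s.sample_id: s.purity for s in manifest.samples}
    regions = region_grid(segments_by_sample)
    # Informative variants: somatic calls the sample actually carries.
    carried = {
        sid: [v for v in somatic_by_sample[sid]
              if call_presence(v.alt_depth, v.total_depth,
                               vaf_cut=params.vaf_cut,
                               min_depth=params.min_depth_presence)
              == "present"]
        for sid in sample_ids
    }
    scopes: list[LohScope] = []
    for chrom, start, end in regions:
        calls = {}
        for sid in included_all:
            seg = _containing_segment(segments_by_sample[sid], chrom, start, end)
            if seg is None:
                continue
            in_region = [v for v in carried[sid]
                         if v.chrom == chrom and start <= v.pos < end]
            calls[sid] = classify_segment_zygosity(
                seg, in_region, purity=purity[sid], params=params.zygosity)
        if not calls:
            continue
        try:
            scopes.append(classify_loh_scope((chrom, start, end), calls))
        except ValueError:
            continue  # all calls indeterminate: region stays unclassified

    # --- stage 6: maintenance statistics ------------------------------------
    pam_positions = {pid: (pam_variants[pid].chrom, pam_variants[pid].pos)
                     for pid in pam_ids}
    pct_truncal = {sid: percent_truncal(sid, presence, truncal)
                   for sid in included_mets}
    pm_values = {pid: percent_maintained(pid, presence, included_mets)
                 for pid in sorted(truncal.pam_ids)}
    by_class = maintenance_by_loh_class(presence, truncal, scopes,
                                        pam_positions, included_mets)
    lesions = presence.subset_samples(included_all)
    shared = shared_by_all(truncal, lesions)

    overlaps_raw = set_overlaps(
        {sid: presence.present_set(sid) for sid in included_all}
    ) if 2 <= len(included_all) <= 7 else {}
    overlaps = {"+".join(sorted(k)): v for k, v in overlaps_raw.items()}

    # Per-arm tables for every included tumor sample.
    arm_frames = []
    truncal_positions = [pam_positions[p] for p in sorted(truncal.pam_ids)
                         if p in pam_positions]
    for sid in included_all:
        variants_by_key = {(v.chrom, v.pos): v
                           for v in records_by_sample[sid]}
        present_map = {
            pam_positions[p]: (p in presence.present_set(sid))
            for p in sorted(truncal.pam_ids) if p in pam_positions
        }
        arm_frames.append(per_arm_summary(
            sid, truncal_positions, variants_by_key,
            segments_by_sample[sid], arms, present_map))
    per_arm = pd.concat(arm_frames, ignore_index=True) if arm_frames \
        else pd.DataFrame()

    # Group test: per-PAM maintenance compared across LOH classes.
    tests: dict[str, Any] = {}
    class_groups: dict[str, list[float]] = {}
    for pid, pm in pm_values.items():
        if pm is None or pid not in pam_positions:
            continue
        cls = _scope_of(pam_positions[pid], scopes)
        class_groups.setdefault(cls, []).append(pm)
    usable = {k: v for k, v in class_groups.items()
              if k != "unclassified" and len(v) >= 2}
    if len(usable) >= 2:
        tests["maintenance_by_class"] = group_tests(usable)

    report = CaseReport(
        case_id=manifest.case_id,
        qc=qc,
        truncal_size=len(truncal.pam_ids),
        truncal_provenance=truncal.provenance,
        percent_truncal=pct_truncal,
        percent_maintained_mean=_mean_or_none(pm_values),
        shared_all=shared,
        by_loh_class=by_class,
        loh_scopes=scopes,
        per_arm=per_arm,
        overlaps=overlaps,
        tests=tests,
        provenance={
            "pamtrace_version": __version__,
            "seed": manifest.seed,
            "params": {
                "vaf_cut": params.vaf_cut,
                "min_depth_presence": params.min_depth_presence,
                "high_vaf": params.high_vaf,
                "qc_min_depth": params.qc_min_depth,
            },
        },
    )
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return report


def _containing_segment(segments: list[SegmentRecord], chrom: str,
                        start: int, end: int) -> SegmentRecord | None:
    for seg in segments:
        if seg.chrom == chrom and seg.start <= start and end <= seg.end:
            return seg
    return None


def _scope_of(position: tuple[str, int], scopes: list[LohScope]) -> str:
    chrom, pos = position
    for s in scopes:
        if s.chrom == chrom and s.start <= pos < s.end:
            return s.scope
    return "unclassified"


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("[%(asctime)s] %(name)s %(levelname)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
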