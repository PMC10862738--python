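"""Synthetic metastatic clonal-evolution simulator with known ground truth.

The generative model is a star phylogeny rooted at the cancer-initiating
cell (CIC): trunk mutations are placed on explicit homologs of a diploid
genome, trunk-level copy-number events (copy-loss LOH, copy-neutral LOH,
gains) are applied *before* lineage divergence — so trunk mutations on a
lost homolog vanish from every sample — and each sample then independently
receives private mutations and private copy-number events. Read counts are
sampled per site as Poisson total depth and binomial alt depth at the
expected VAF given purity, local copy number and multiplicity.

The simulator emits the same artifacts a real case provides (reference
FASTA, per-sample VCFs with AD/DP, per-sample copy-number segment tables,
an arm table) plus a truth manifest for parameter-recovery tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io import (ArmEntry, ArmTable, GenomeSequence, SegmentRecord,
                 VariantRecord, write_arm_table, write_fasta, write_segments,
                 write_vcf)
from .loh import expected_vaf
from .pam import detect_novel_pams

__all__ = [
    "SampleSpec",
    "CnEvent",
    "SimulationConfig",
    "HomologState",
    "MutationTruth",
    "RegionTruth",
    "TruthManifest",
    "simulate_reference",
    "simulate_case",
    "emit_sample",
    "emit_case",
    "load_scenario",
    "bundled_scenario_path",
    "DEFAULT_SPECTRUM",
]

_BASES = ("A", "C", "G", "T")

# Transition:transversion ratio 2:1 overall — each of the 4 transition
# classes carries (2/3)/4, each of the 8 transversion classes (1/3)/8.
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
DEFAULT_SPECTRUM: dict[str, float] = {
    f"{r}>{a}": (1 / 6 if (r, a) in _TRANSITIONS else 1 / 24)
    for r in _BASES for a in _BASES if r != a
}


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    role: str  # primary | metastasis | normal
    purity: float = 1.0
    mean_depth: float = 60.0

    def __post_init__(self) -> None:
        if self.role not in ("primary", "metastasis", "normal"):
            raise ValueError(f"bad role {self.role!r}")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")


@dataclass(frozen=True)
class CnEvent:
    """A copy-number event on one region.

    ``target`` is "trunk" (applied in the CIC, before divergence) or a
    sample id (private). ``kind`` is copy_loss, copy_neutral (LOH without
    copy change) or gain (to ``new_cn`` copies).
    """

    chrom: str
    start: int
    end: int
    kind: str  # copy_loss | copy_neutral | gain
    target: str = "trunk"
    new_cn: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("copy_loss", "copy_neutral", "gain"):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.kind == "gain" and (self.new_cn is None or self.new_cn < 3):
            raise ValueError("gain events need new_cn >= 3")
        if self.start >= self.end:
            raise ValueError("empty event region")

    def overlaps(self, other: "CnEvent") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 1_000_000
    gc_content: float = 0.41
    n_trunk_mutations: int = 300
    n_private_mutations: int = 60  # per tumor sample
    samples: list[SampleSpec] = field(default_factory=list)
    cn_events: list[CnEvent] = field(default_factory=list)
    mutation_spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM))
    arm_fraction: float = 0.5
    capture_panel: bool = True
    case_id: str = "SIM"

    def __post_init__(self) -> None:
        total = sum(self.mutation_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mutation spectrum sums to {total}, not 1")
        names = [s.sample_id for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample ids")
        self._check_events()

    def _check_events(self) -> None:
        chroms = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for e in self.cn_events:
            if e.chrom not in chroms:
                raise ValueError(f"event chromosome {e.chrom!r} not simulated")
            if e.end > self.chrom_length:
                raise ValueError(f"event region beyond chromosome end: {e}")
        # Two events with the same target may not overlap (contradictory);
        # a trunk event overlapped by a later private event is fine — they
        # apply sequentially (e.g. trunk gain then private loss).
        for i, a in enumerate(self.cn_events):
            for b in self.cn_events[i + 1:]:
                if a.overlaps(b) and a.target == b.target:
                    raise ValueError(
                        f"overlapping contradictory CN events: {a} vs {b}"
                    )

    @property
    def tumor_samples(self) -> list[SampleSpec]:
        return [s for s in self.samples if s.role != "normal"]

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


# ---------------------------------------------------------------------------
# Homolog bookkeeping


@dataclass
class HomologSegment:
    start: int
    end: int
    copies: tuple[str, ...]  # e.g. ("h1", "h2"), ("h2", "h2", "h2")


class HomologState:
    """Per-chromosome partition into segments of surviving homolog copies."""

    def __init__(self, chrom_names: Sequence[str], chrom_length: int) -> None:
        self.segments: dict[str, list[HomologSegment]] = {
            c: [HomologSegment(0, chrom_length, ("h1", "h2"))]
            for c in chrom_names
        }

    def clone(self) -> "HomologState":
        new = object.__new__(HomologState)
        new.segments = {c: [copy.copy(s) for s in segs]
                        for c, segs in self.segments.items()}
        return new

    def _split(self, chrom: str, point: int) -> None:
        out = []
        for seg in self.segments[chrom]:
            if seg.start < point < seg.end:
                out.append(HomologSegment(seg.start, point, seg.copies))
                out.append(HomologSegment(point, seg.end, seg.copies))
            else:
                out.append(seg)
        self.segments[chrom] = out

    def apply_event(self, event: CnEvent, rng: np.random.Generator,
                    distinct_gain: bool = False) -> None:
        self._split(event.chrom, event.start)
        self._split(event.chrom, event.end)
        for seg in self.segments[event.chrom]:
            if seg.start >= event.start and seg.end <= event.end:
                seg.copies = _transform_copies(seg.copies, event, rng,
                                               distinct_gain=distinct_gain)

    def copies_at(self, chrom: str, pos: int) -> tuple[str, ...]:
        for seg in self.segments[chrom]:
            if seg.start <= pos < seg.end:
                return seg.copies
        raise KeyError(f"{chrom}:{pos} outside simulated genome")

    def segment_records(self, sample_id: str) -> list[SegmentRecord]:
        # Adjacent equal-CN segments are kept separate: segmentation in CN
        # callers retains breakpoints that integer rounding later equalises,
        # and copy-neutral LOH boundaries are exactly such breakpoints.
        return [
            SegmentRecord(chrom=chrom, start=seg.start, end=seg.end,
                          total_cn=len(seg.copies), sample_id=sample_id)
            for chrom, segs in self.segments.items() for seg in segs
        ]


def _transform_copies(copies: tuple[str, ...], event: CnEvent,
                      rng: np.random.Generator,
                      distinct_gain: bool = False) -> tuple[str, ...]:
    """Apply one CN event to a homolog multiset.

    Loss events remove one physical copy chosen uniformly at random — this
    uniform choice, not a fitted parameter, is what produces the 1/2 loss
    rate of multiplicity-1 sites in diploid regions and 1/3 in triploid.

    Gains duplicate one copy. ``distinct_gain`` gives the new copies fresh
    labels: used for ancestral (pre-mutation) gains, where later mutations
    land on individual physical copies with multiplicity 1. A gain applied
    after mutation placement keeps the parent label, so existing mutations
    on it are duplicated (multiplicity follows the label count).
    """
    copies = list(copies)
    if not copies:
        return tuple(copies)
    if event.kind == "copy_loss":
        lost = int(rng.integers(len(copies)))
        del copies[lost]
    elif event.kind == "copy_neutral":
        if len(copies) < 2:
            return tuple(copies)
        lost = int(rng.integers(len(copies)))
        del copies[lost]
        dup = copies[int(rng.integers(len(copies)))]
        copies.append(dup)
        copies.sort()
    else:  # gain
        assert event.new_cn is not None
        dup = copies[int(rng.integers(len(copies)))]
        k = 0
        while len(copies) < event.new_cn:
            k += 1
            copies.append(f"{dup}.{k}" if distinct_gain else dup)
        copies.sort()
    return tuple(copies)


# ---------------------------------------------------------------------------
# Truth containers


@dataclass
class SiteTruth:
    cn: int
    multiplicity: int
    expected_vaf: float
    survived: bool


@dataclass
class MutationTruth:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    homolog: str
    origin: str  # "trunk" or the owning sample id
    creating_pam: bool
    per_sample: dict[str, SiteTruth] = field(default_factory=dict)

    @property
    def mutation_id(self) -> str:
        return f"{self.chrom}:{self.pos + 1}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class RegionTruth:
    chrom: str
    start: int
    end: int
    scope: str  # truncal_loh | private_loh | retained_het
    mode: str  # copy_loss | copy_neutral | not_applicable


@dataclass
class TruthManifest:
    case_id: str
    mutations: list[MutationTruth]
    regions: list[RegionTruth]
    homolog_states: dict[str, HomologState]  # per tumor sample
    reference: list[GenomeSequence] = field(default_factory=list)
    arms: ArmTable | None = None

    def trunk_mutations(self) -> list[MutationTruth]:
        return [m for m in self.mutations if m.origin == "trunk"]

    def write_tsv(self, path: str | Path, sample_ids: Sequence[str]) -> None:
        lines = ["\t".join(
            ["mutation_id", "chrom", "pos", "ref", "alt", "homolog", "origin",
             "creating_pam"]
            + [f"{s}:{f}" for s in sample_ids
               for f in ("cn", "mult", "evaf", "survived")]
        )]
        for m in sorted(self.mutations, key=lambda m: (m.chrom, m.pos)):
            row = [m.mutation_id, m.chrom, str(m.pos + 1), m.ref, m.alt,
                   m.homolog, m.origin, str(int(m.creating_pam))]
            for s in sample_ids:
                t = m.per_sample[s]
                row += [str(t.cn), str(t.multiplicity), f"{t.expected_vaf:.6g}",
                        str(int(t.survived))]
            lines.append("\t".join(row))
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Simulation


def simulate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[list[GenomeSequence], ArmTable]:
    """I.i.d. reference at the configured GC content, plus an arm table
    splitting each chromosome at ``arm_fraction``. Deterministic per seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs: list[GenomeSequence] = []
    entries: list[ArmEntry] = []
    for name in config.chrom_names:
        bases = rng.choice(np.array(list("ACGT")), size=config.chrom_length,
                           p=probs)
        seqs.append(GenomeSequence(name=name, sequence="".join(bases)))
        mid = int(config.chrom_length * config.arm_fraction)
        mid = min(max(mid, 1), config.chrom_length - 1)
        entries.append(ArmEntry(chrom=name, arm="p", start=0, end=mid))
        entries.append(ArmEntry(chrom=name, arm="q", start=mid,
                                end=config.chrom_length))
    return seqs, ArmTable(entries=entries)


def _draw_alt(ref: str, spectrum: Mapping[str, float],
              rng: np.random.Generator) -> str:
    alts = [a for a in _BASES if a != ref]
    weights = np.array([spectrum[f"{ref}>{a}"] for a in alts], dtype=float)
    weights /= weights.sum()
    return alts[int(rng.choice(3, p=weights))]


def simulate_case(config: SimulationConfig
                  ) -> tuple[TruthManifest, dict[str, HomologState]]:
    """Run the generative model and return ground truth per mutation/region.

    Order of operations: place trunk mutations on homologs → apply trunk CN
    events (truncal LOH before divergence) → per sample, apply private CN
    events then place private mutations → record per-sample copy number,
    multiplicity, expected VAF and survival for every mutation.
    """
    rng = np.random.default_rng(config.seed)
    reference, arms = simulate_reference(config, rng)
    ref_by_name = {s.name: s for s in reference}
    tumor = config.tumor_samples
    if not tumor:
        raise ValueError("config lists no tumor samples")

    # --- mutation positions, unique genome-wide -----------------------------
    genome_len = config.n_chromosomes * config.chrom_length
    n_private_total = config.n_private_mutations * len(tumor)
    n_total = config.n_trunk_mutations + n_private_total
    if n_total > genome_len:
        raise ValueError("more mutations requested than genome positions")
    flat = rng.choice(genome_len, size=n_total, replace=False)
    positions = [(config.chrom_names[p // config.chrom_length],
                  int(p % config.chrom_length)) for p in flat]

    def make_mutation(chrom: str, pos: int, homolog: str, origin: str
                      ) -> MutationTruth:
        ref_base = ref_by_name[chrom].sequence[pos]
        alt = _draw_alt(ref_base, config.mutation_spectrum, rng)
        probe = VariantRecord(chrom=chrom, pos=pos, ref=ref_base, alt=alt,
                              sample_id="truth", alt_depth=1, total_depth=1)
        creating = bool(detect_novel_pams(probe, ref_by_name[chrom]))
        return MutationTruth(chrom=chrom, pos=pos, ref=ref_base, alt=alt,
                             homolog=homolog, origin=origin,
                             creating_pam=creating)

    # --- trunk --------------------------------------------------------------
    # Ancestral (trunk) gains set the CIC karyotype before mutation
    # placement: each gained copy is a distinct physical chromosome, so
    # trunk mutations in gained regions have multiplicity 1 on one of the
    # local copies. Truncal LOH events apply after placement — trunk
    # mutations on the lost homolog vanish from every sample.
    trunk_state = HomologState(config.chrom_names, config.chrom_length)
    for event in config.cn_events:
        if event.target == "trunk" and event.kind == "gain":
            trunk_state.apply_event(event, rng, distinct_gain=True)

    trunk_positions = positions[:config.n_trunk_mutations]
    mutations: list[MutationTruth] = []
    for chrom, pos in trunk_positions:
        copies = trunk_state.copies_at(chrom, pos)
        homolog = copies[int(rng.integers(len(copies)))]
        mutations.append(make_mutation(chrom, pos, homolog=homolog,
                                       origin="trunk"))

    for event in config.cn_events:
        if event.target == "trunk" and event.kind != "gain":
            trunk_state.apply_event(event, rng)

    # --- per-sample divergence ----------------------------------------------
    states: dict[str, HomologState] = {}
    offset = config.n_trunk_mutations
    for spec in tumor:
        state = trunk_state.clone()
        for event in config.cn_events:
            if event.target == spec.sample_id:
                state.apply_event(event, rng)
        states[spec.sample_id] = state

        own = positions[offset:offset + config.n_private_mutations]
        offset += config.n_private_mutations
        for chrom, pos in own:
            copies = state.copies_at(chrom, pos)
            if not copies:
                continue  # fully deleted locus cannot mutate
            homolog = copies[int(rng.integers(len(copies)))]
            m = make_mutation(chrom, pos, homolog=homolog,
                              origin=spec.sample_id)
            mutations.append(m)

    # --- per-sample truth ---------------------------------------------------
    for m in mutations:
        for spec in tumor:
            state = states[spec.sample_id]
            copies = state.copies_at(m.chrom, m.pos)
            cn = len(copies)
            if m.origin == "trunk":
                mult = copies.count(m.homolog)
            else:
                # Private mutations are physical single-copy events in their
                # own sample and never exist elsewhere.
                mult = 1 if (m.origin == spec.sample_id
                             and m.homolog in copies) else 0
            if mult == 0 or cn == 0:
                evaf = (0.0 if spec.purity >= 1.0 or cn == 0
                        else expected_vaf(spec.purity, cn, 0))
            else:
                evaf = expected_vaf(spec.purity, cn, mult)
            m.per_sample[spec.sample_id] = SiteTruth(
                cn=cn, multiplicity=mult, expected_vaf=evaf,
                survived=mult >= 1)

    regions = _region_truth(config, states)
    manifest = TruthManifest(case_id=config.case_id, mutations=mutations,
                             regions=regions, homolog_states=states,
                             reference=reference, arms=arms)
    return manifest, states


def _region_truth(config: SimulationConfig,
                  states: Mapping[str, HomologState]) -> list[RegionTruth]:
    """Scope labels from the final per-sample homolog states.

    A sample-region is LOH when every surviving copy carries the same label
    — exactly the condition under which all trunk variants there sit at the
    m = C_T VAF peak. A triploid region that loses one of three *distinct*
    copies keeps two different copies and therefore stays heterozygous
    (its multiplicity-1 sites are still lost at 1/3), while copy-neutral
    LOH duplicates the remaining homolog and is LOH at CN 2.
    """
    out: list[RegionTruth] = []
    for chrom in config.chrom_names:
        points = {0, config.chrom_length}
        for e in config.cn_events:
            if e.chrom == chrom:
                points.update((e.start, e.end))
        for a, b in zip(sorted(points), sorted(points)[1:]):
            loh: dict[str, bool] = {}
            cns: dict[str, int] = {}
            for sid, state in states.items():
                copies = state.copies_at(chrom, a)
                cns[sid] = len(copies)
                loh[sid] = len(copies) >= 1 and len(set(copies)) == 1
            if all(loh.values()):
                scope = "truncal_loh"
                loh_cns = [cns[s] for s in loh]
            elif any(loh.values()):
                scope = "private_loh"
                loh_cns = [cns[s] for s, flag in loh.items() if flag]
            else:
                scope = "retained_het"
                loh_cns = []
            if not loh_cns:
                mode = "not_applicable"
            elif all(c <= 1 for c in loh_cns):
                mode = "copy_loss"
            elif all(c >= 2 for c in loh_cns):
                mode = "copy_neutral"
            else:
                mode = "mixed"
            out.append(RegionTruth(chrom, a, b, scope, mode))
    return out


# ---------------------------------------------------------------------------
# Read sampling / emission


def emit_sample(
    manifest: TruthManifest,
    sample: SampleSpec,
    config: SimulationConfig,
    outdir: str | Path,
    contigs: Sequence[tuple[str, int]],
    panel: Sequence[MutationTruth] | None = None,
) -> tuple[Path, Path]:
    """Sample reads for one tumor sample and write its VCF + segment table.

    Whole-genome mode writes only mutations surviving in the sample;
    capture-panel mode additionally writes zero-alt records at every panel
    position so presence/absence calling is exercised downstream. Depth is
    Poisson(mean_depth), alt count Binomial(depth, expected VAF); a
    dedicated RNG stream per sample keeps emission deterministic per seed
    and independent of sample order.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_index = [s.sample_id for s in config.samples].index(sample.sample_id)
    rng = np.random.default_rng([config.seed, 7919, sample_index])

    sites: list[MutationTruth]
    if panel is not None:
        sites = list(panel)
    else:
        sites = [m for m in manifest.mutations
                 if m.per_sample[sample.sample_id].survived]

    records: list[VariantRecord] = []
    for m in sorted(sites, key=lambda m: (m.chrom, m.pos, m.alt)):
        truth = m.per_sample[sample.sample_id]
        depth = int(rng.poisson(sample.mean_depth))
        if depth == 0:
            if panel is None:
                continue
            alt = 0
        else:
            alt = int(rng.binomial(depth, truth.expected_vaf))
        if panel is None and alt == 0:
            continue  # a caller would not report an alt-free site
        records.append(
            VariantRecord(chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                          sample_id=sample.sample_id, alt_depth=alt,
                          total_depth=depth)
        )

    vcf_path = outdir / f"{sample.sample_id}.vcf"
    write_vcf(records, vcf_path, sample=sample.sample_id, contigs=contigs)
    seg_path = outdir / f"{sample.sample_id}.cns"
    segs = manifest.homolog_states[sample.sample_id].segment_records(
        sample.sample_id)
    write_segments(segs, seg_path)
    return vcf_path, seg_path


def emit_case(config: SimulationConfig, outdir: str | Path
              ) -> dict[str, Path]:
    """Simulate and write a complete case: ref.fa, arms.bed, per-sample VCF
    and .cns, an (empty) normal VCF, and truth.tsv. Returns output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest, _states = simulate_case(config)
    reference, arms = manifest.reference, manifest.arms
    assert arms is not None
    contigs = [(s.name, len(s)) for s in reference]

    paths: dict[str, Path] = {}
    ref_path = outdir / "ref.fa"
    write_fasta(reference, ref_path)
    paths["reference"] = ref_path
    arm_path = outdir / "arms.bed"
    write_arm_table(arms, arm_path)
    paths["arms"] = arm_path

    panel = sorted(manifest.mutations, key=lambda m: (m.chrom, m.pos)) \
        if config.capture_panel else None
    for spec in config.tumor_samples:
        vcf, cns = emit_sample(manifest, spec, config, outdir, contigs,
                               panel=panel)
        paths[f"{spec.sample_id}.vcf"] = vcf
        paths[f"{spec.sample_id}.cns"] = cns

    normals = [s for s in config.samples if s.role == "normal"]
    normal_id = normals[0].sample_id if normals else "normal"
    normal_path = outdir / f"{normal_id}.vcf"
    write_vcf([], normal_path, sample=normal_id, contigs=contigs)
    paths["normal"] = normal_path

    truth_path = outdir / "truth.tsv"
    manifest.write_tsv(truth_path,
                       [s.sample_id for s in config.tumor_samples])
    paths["truth"] = truth_path

    # Ready-to-run case manifest for the analysis pipeline.
    case_manifest = {
        "case_id": config.case_id,
        "reference": "ref.fa",
        "arms": "arms.bed",
        "normal_vcf": normal_path.name,
        "normal_sample": normal_id,
        "seed": config.seed,
        "samples": [
            {"sample_id": s.sample_id, "role": s.role,
             "vcf": f"{s.sample_id}.vcf", "segments": f"{s.sample_id}.cns",
             "purity": s.purity}
            for s in config.tumor_samples
        ],
    }
    manifest_path = outdir / "case.yaml"
    manifest_path.write_text(
        yaml.safe_dump(case_manifest, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths


# ---------------------------------------------------------------------------
# Scenario files


def load_scenario(path: str | Path, seed: int | None = None
                  ) -> SimulationConfig:
    """Load a scenario YAML into a SimulationConfig; ``seed`` overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
    events = [CnEvent(**e) for e in raw.pop("cn_events", [])]
    spectrum = raw.pop("mutation_spectrum", None)
    config = SimulationConfig(
        samples=samples, cn_events=events,
        mutation_spectrum=spectrum or dict(DEFAULT_SPECTRUM), **raw)
    if seed is not None:
        config = replace_seed(config, seed)
    return config


def replace_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    new = copy.copy(config)
    new.seed = seed
    return new


def bundled_scenario_path(name: str) -> Path:
    """Path of a scenario shipped with the package (e.g. "a38_like")."""
    from importlib import resources

    ref = resources.files("pamtrace") / "scenarios" / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return Path(p)
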