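import numpy as np
import pytest

from pamtrace.io import read_segments, read_vcf
from pamtrace.simulate import (CnEvent, SampleSpec, SimulationConfig,
                               bundled_scenario_path, emit_case, emit_sample,
                               load_scenario, simulate_case,
                               simulate_reference)


def config(**overrides):
    base = dict(
        seed=3, n_chromosomes=1, chrom_length=100_000,
        n_trunk_mutations=500, n_private_mutations=0,
        samples=[SampleSpec("P1", "primary"),
                 SampleSpec("M1", "metastasis")],
        cn_events=[],
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestReference:
    def test_deterministic_per_seed(self):
        cfg = config()
        (a,), _ = simulate_reference(cfg)
        (b,), _ = simulate_reference(cfg)
        assert a.sequence == b.sequence

    def test_gc_zero_limit(self):
        (s,), _ = simulate_reference(config(gc_content=0.0))
        assert set(s.sequence) <= {"A", "T"}

    def test_empirical_gc_content(self):
        cfg = config(chrom_length=1_000_000, gc_content=0.41)
        (s,), _ = simulate_reference(cfg)
        gc = (s.sequence.count("G") + s.sequence.count("C")) / len(s.sequence)
        se = np.sqrt(0.41 * 0.59 / len(s.sequence))
        assert abs(gc - 0.41) < 3 * se

    def test_arm_table_splits_at_fraction(self):
        _, arms = simulate_reference(config(arm_fraction=0.25))
        p = next(e for e in arms.entries if e.arm == "p")
        q = next(e for e in arms.entries if e.arm == "q")
        assert (p.start, p.end) == (0, 25_000)
        assert (q.start, q.end) == (25_000, 100_000)


class TestCaseGeneration:
    def test_null_model_everything_survives_heterozygous(self):
        manifest, _ = simulate_case(config())
        for m in manifest.trunk_mutations():
            for sid in ("P1", "M1"):
                t = m.per_sample[sid]
                assert t.survived
                assert (t.cn, t.multiplicity) == (2, 1)
                assert t.expected_vaf == 0.5

    def test_truncal_copy_loss(self):
        cfg = config(cn_events=[
            CnEvent("chr1", 0, 100_000, "copy_loss", target="trunk")])
        manifest, _ = simulate_case(cfg)
        trunk = manifest.trunk_mutations()
        survived = [m for m in trunk if m.per_sample["P1"].survived]
        # survivors sit at VAF 1, CN 1 in every sample
        for m in survived:
            for sid in ("P1", "M1"):
                t = m.per_sample[sid]
                assert (t.cn, t.multiplicity, t.expected_vaf) == (1, 1, 1.0)
        # lost mutations are lost in all samples (LOH precedes divergence)
        for m in trunk:
            assert m.per_sample["P1"].survived == m.per_sample["M1"].survived
        frac = len(survived) / len(trunk)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(trunk))

    def test_truncal_copy_neutral(self):
        cfg = config(cn_events=[
            CnEvent("chr1", 0, 100_000, "copy_neutral", target="trunk")])
        manifest, _ = simulate_case(cfg)
        for m in manifest.trunk_mutations():
            t = m.per_sample["M1"]
            if t.survived:
                assert (t.cn, t.multiplicity, t.expected_vaf) == (2, 2, 1.0)

    def test_private_copy_loss_halves_only_that_sample(self,
                                                       two_sample_config):
        manifest, _ = simulate_case(two_sample_config)
        trunk = manifest.trunk_mutations()
        assert all(m.per_sample["P1"].survived for m in trunk)
        lost = [m for m in trunk if not m.per_sample["M1"].survived]
        frac = len(lost) / len(trunk)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(trunk))
        for m in trunk:
            t = m.per_sample["M1"]
            if t.survived:
                assert (t.cn, t.expected_vaf) == (1, 1.0)
            else:
                assert (t.cn, t.multiplicity) == (1, 0)

    def test_ancestral_gain_gives_multiplicity_one_triploid(self):
        cfg = config(cn_events=[
            CnEvent("chr1", 0, 100_000, "gain", target="trunk", new_cn=3)])
        manifest, _ = simulate_case(cfg)
        for m in manifest.trunk_mutations():
            t = m.per_sample["P1"]
            assert (t.cn, t.multiplicity) == (3, 1)
            assert t.expected_vaf == pytest.approx(1 / 3)

    def test_triploid_private_loss_one_third(self):
        cfg = config(
            n_trunk_mutations=3000,
            cn_events=[
                CnEvent("chr1", 0, 100_000, "gain", target="trunk", new_cn=3),
                CnEvent("chr1", 0, 100_000, "copy_loss", target="M1"),
            ])
        manifest, _ = simulate_case(cfg)
        trunk = manifest.trunk_mutations()
        lost = [m for m in trunk if not m.per_sample["M1"].survived]
        frac = len(lost) / len(trunk)
        assert abs(frac - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / len(trunk))

    def test_private_mutations_absent_elsewhere(self):
        cfg = config(n_private_mutations=50)
        manifest, _ = simulate_case(cfg)
        privates = [m for m in manifest.mutations if m.origin != "trunk"]
        assert len(privates) == 100
        for m in privates:
            own = m.origin
            other = "M1" if own == "P1" else "P1"
            assert m.per_sample[own].survived
            assert not m.per_sample[other].survived

    def test_pam_fraction_matches_composition_oracle(self):
        """Fraction of SBS creating PAMs matches the closed-form expectation
        for the spectrum and base composition, within 3 SE."""
        cfg = config(n_trunk_mutations=2000, chrom_length=200_000)
        manifest, _ = simulate_case(cfg)
        (ref,) = manifest.reference
        seq = ref.sequence
        pi = {b: seq.count(b) / len(seq) for b in "ACGT"}
        q = {"G": 1 - (1 - pi["G"]) ** 2, "C": 1 - (1 - pi["C"]) ** 2,
             "A": 0.0, "T": 0.0}
        spec = cfg.mutation_spectrum
        expect = 0.0
        for r in "ACGT":
            alts = [a for a in "ACGT" if a != r]
            norm = sum(spec[f"{r}>{a}"] for a in alts)
            expect += pi[r] * sum(
                spec[f"{r}>{a}"] / norm * q[a] for a in alts)
        observed = np.mean([m.creating_pam for m in manifest.mutations])
        se = np.sqrt(expect * (1 - expect) / len(manifest.mutations))
        assert abs(observed - expect) < 3 * se

    def test_region_truth_labels(self):
        cfg = config(
            n_chromosomes=3,
            cn_events=[
                CnEvent("chr1", 0, 100_000, "copy_loss", target="trunk"),
                CnEvent("chr2", 0, 50_000, "copy_loss", target="M1"),
            ])
        manifest, _ = simulate_case(cfg)
        scopes = {(r.chrom, r.start, r.end): r.scope for r in manifest.regions}
        assert scopes[("chr1", 0, 100_000)] == "truncal_loh"
        assert scopes[("chr2", 0, 50_000)] == "private_loh"
        assert scopes[("chr2", 50_000, 100_000)] == "retained_het"
        assert scopes[("chr3", 0, 100_000)] == "retained_het"

    def test_contradictory_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            config(cn_events=[
                CnEvent("chr1", 0, 50_000, "copy_loss", target="M1"),
                CnEvent("chr1", 40_000, 90_000, "copy_neutral", target="M1"),
            ])


class TestEmission:
    def test_full_vaf_sites_have_all_alt_reads(self, tmp_path):
        cfg = config(cn_events=[
            CnEvent("chr1", 0, 100_000, "copy_loss", target="trunk")])
        manifest, _ = simulate_case(cfg)
        contigs = [(s.name, len(s)) for s in manifest.reference]
        vcf, _ = emit_sample(manifest, cfg.samples[1], cfg, tmp_path, contigs)
        records, _ = read_vcf(vcf, "M1")
        surviving = {(m.chrom, m.pos) for m in manifest.trunk_mutations()
                     if m.per_sample["M1"].survived}
        for r in records:
            if (r.chrom, r.pos) in surviving:
                assert r.alt_depth == r.total_depth

    def test_segment_file_reflects_events(self, tmp_path):
        cfg = config(cn_events=[
            CnEvent("chr1", 20_000, 60_000, "copy_loss", target="M1")])
        manifest, _ = simulate_case(cfg)
        contigs = [(s.name, len(s)) for s in manifest.reference]
        _, cns = emit_sample(manifest, cfg.samples[1], cfg, tmp_path, contigs)
        segs = read_segments(cns, sample="M1")
        assert [(s.start, s.end, s.total_cn) for s in segs] == \
            [(0, 20_000, 2), (20_000, 60_000, 1), (60_000, 100_000, 2)]

    def test_purity_dilutes_mean_vaf(self, tmp_path):
        cfg = config(
            n_trunk_mutations=800,
            samples=[SampleSpec("P1", "primary"),
                     SampleSpec("M1", "metastasis", purity=0.5,
                                mean_depth=80)])
        manifest, _ = simulate_case(cfg)
        contigs = [(s.name, len(s)) for s in manifest.reference]
        vcf, _ = emit_sample(manifest, cfg.samples[1], cfg, tmp_path, contigs)
        records, _ = read_vcf(vcf, "M1")
        mean_vaf = np.mean([r.vaf for r in records])
        # diploid het site at purity 0.5: expected VAF 0.25
        assert abs(mean_vaf - 0.25) < 0.02

    def test_zero_depth_capture_records_no_callable(self, tmp_path):
        cfg = config(
            n_trunk_mutations=50,
            samples=[SampleSpec("P1", "primary"),
                     SampleSpec("M1", "metastasis", mean_depth=0.0)])
        manifest, _ = simulate_case(cfg)
        contigs = [(s.name, len(s)) for s in manifest.reference]
        panel = manifest.trunk_mutations()
        vcf, _ = emit_sample(manifest, cfg.samples[1], cfg, tmp_path, contigs,
                             panel=panel)
        records, _ = read_vcf(vcf, "M1")
        assert len(records) == 50
        assert all(r.total_depth == 0 for r in records)

    def test_byte_identical_reruns(self, tmp_path):
        cfg = config(n_trunk_mutations=200, n_private_mutations=20)
        out_a = emit_case(cfg, tmp_path / "a")
        out_b = emit_case(cfg, tmp_path / "b")
        assert out_a.keys() == out_b.keys()
        for key in out_a:
            assert out_a[key].read_bytes() == out_b[key].read_bytes(), key

    def test_different_seed_changes_output(self, tmp_path):
        cfg_a = config(seed=1)
        cfg_b = config(seed=2)
        a = emit_case(cfg_a, tmp_path / "a")
        b = emit_case(cfg_b, tmp_path / "b")
        assert a["reference"].read_bytes() != b["reference"].read_bytes()


class TestScenarios:
    @pytest.mark.parametrize("name", ["a38_like", "full_case"])
    def test_bundled_scenarios_load(self, name):
        cfg = load_scenario(bundled_scenario_path(name))
        assert cfg.tumor_samples
        assert abs(sum(cfg.mutation_spectrum.values()) - 1) < 1e-9

    def test_seed_override(self):
        cfg = load_scenario(bundled_scenario_path("a38_like"), seed=99)
        assert cfg.seed == 99
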