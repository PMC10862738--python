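"""Simulate a metastatic case with known ground truth.

A star phylogeny from the cancer-initiating cell: trunk mutations on
explicit homologs, truncal LOH applied before divergence, then per-sample
private events. The truth manifest records survival and expected VAF of
every mutation in every sample.
"""

from pamtrace import CnEvent, SampleSpec, SimulationConfig, simulate_case

config = SimulationConfig(
    seed=42, n_chromosomes=2, chrom_length=400_000,
    n_trunk_mutations=2000, n_private_mutations=0,
    samples=[SampleSpec("P1", "primary"), SampleSpec("M1", "metastasis")],
    cn_events=[
        # chr1: truncal copy-loss LOH (before divergence)
        CnEvent("chr1", 0, 400_000, "copy_loss", target="trunk"),
        # chr2: private copy-loss LOH in the metastasis only
        CnEvent("chr2", 0, 400_000, "copy_loss", target="M1"),
    ],
)
manifest, _ = simulate_case(config)
trunk = manifest.trunk_mutations()

by_chrom = {"chr1": [], "chr2": []}
for m in trunk:
    by_chrom[m.chrom].append(m)

chr1_surv = [m for m in by_chrom["chr1"] if m.per_sample["P1"].survived]
print(f"chr1 (truncal LOH): {len(chr1_surv)}/{len(by_chrom['chr1'])} trunk "
      "mutations survive — the rest sat on the homolog lost in the trunk "
      "and vanish from every sample")
print("  survivors in M1 at VAF "
      f"{chr1_surv[0].per_sample['M1'].expected_vaf:.1f}, CN "
      f"{chr1_surv[0].per_sample['M1'].cn} -> 100% maintained, VAF 1")

lost_m1 = [m for m in by_chrom["chr2"] if not m.per_sample["M1"].survived]
print(f"chr2 (private LOH in M1): {len(lost_m1)}/{len(by_chrom['chr2'])} "
      f"trunk mutations lost in M1 ({100 * len(lost_m1) / len(by_chrom['chr2']):.1f}% — "
      "the lost homolog is chosen at random, so ~50%); all survive in P1: "
      f"{all(m.per_sample['P1'].survived for m in by_chrom['chr2'])}")

n_pam = sum(m.creating_pam for m in trunk)
print(f"{n_pam}/{len(trunk)} trunk mutations create novel PAMs "
      f"({100 * n_pam / len(trunk):.1f}%)")
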