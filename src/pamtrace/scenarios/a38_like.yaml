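# Miniature four-sample case patterned on a pancreatic-cancer patient with
# one chromosome under truncal copy-loss LOH (applied before lineage
# divergence), one chromosome under private copy-loss LOH in a single
# metastasis, and one chromosome retaining heterozygosity everywhere.
# Mutation density is far above genome-wide somatic density so that
# megabase-scale chromosomes carry enough informative sites per segment.
case_id: A38LIKE
seed: 7
n_chromosomes: 3
chrom_length: 1000000
gc_content: 0.41
n_trunk_mutations: 600
n_private_mutations: 60
capture_panel: true
samples:
  - {sample_id: P1, role: primary, purity: 1.0, mean_depth: 60}
  - {sample_id: T1, role: metastasis, purity: 1.0, mean_depth: 60}
  - {sample_id: T2, role: metastasis, purity: 1.0, mean_depth: 60}
  - {sample_id: T3, role: metastasis, purity: 1.0, mean_depth: 60}
cn_events:
  # chr1: truncal copy-loss LOH (haploid in every sample, like chromosome 18
  # of the motivating case); chr2: private copy-loss LOH in metastasis T1
  # only; chr3: untouched, retained heterozygosity.
  - {chrom: chr1, start: 0, end: 1000000, kind: copy_loss, target: trunk}
  - {chrom: chr2, start: 0, end: 1000000, kind: copy_loss, target: T1}
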