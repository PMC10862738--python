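# Larger eight-sample case over a 10 Mb genome: two primary sections, five
# metastases (one FFPE-like with low purity and shallow depth, expected to
# fail sample QC), and a matched normal. Exercises truncal copy-loss and
# copy-neutral LOH, private LOH of both modes, a trunk gain with a later
# private loss (triploid -> diploid), and purity dilution.
case_id: FULLCASE
seed: 11
n_chromosomes: 8
chrom_length: 1250000
gc_content: 0.41
n_trunk_mutations: 800
n_private_mutations: 80
capture_panel: true
samples:
  - {sample_id: P1, role: primary, purity: 1.0, mean_depth: 80}
  - {sample_id: P2, role: primary, purity: 1.0, mean_depth: 80}
  - {sample_id: M1, role: metastasis, purity: 1.0, mean_depth: 60}
  - {sample_id: M2, role: metastasis, purity: 1.0, mean_depth: 60}
  - {sample_id: M3, role: metastasis, purity: 1.0, mean_depth: 60}
  - {sample_id: M4, role: metastasis, purity: 1.0, mean_depth: 60}
  - {sample_id: M5, role: metastasis, purity: 0.3, mean_depth: 12}
  - {sample_id: N, role: normal, purity: 1.0, mean_depth: 30}
cn_events:
  - {chrom: chr1, start: 0, end: 1250000, kind: copy_loss, target: trunk}
  - {chrom: chr2, start: 0, end: 625000, kind: copy_neutral, target: trunk}
  - {chrom: chr3, start: 0, end: 1250000, kind: copy_loss, target: M1}
  - {chrom: chr4, start: 0, end: 625000, kind: copy_neutral, target: M2}
  - {chrom: chr5, start: 0, end: 1250000, kind: gain, target: trunk, new_cn: 3}
  - {chrom: chr5, start: 0, end: 1250000, kind: copy_loss, target: M3}
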