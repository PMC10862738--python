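# pamtrace

Tumor-specific CRISPR PAM targets across a patient's metastases: discovery,
loss-of-heterozygosity classification, and clonal maintenance statistics,
with a bundled metastatic clonal-evolution simulator for end-to-end
validation against known ground truth.

## The problem

A somatic single-base substitution (SBS) can turn a germline trinucleotide
such as `NTG` into `NGG` — a protospacer adjacent motif (PAM) recognized by
SpCas9 that exists only in the tumor genome. Such *novel PAMs* are
tumor-specific CRISPR-Cas9 cut sites, and a handful of simultaneous
double-strand breaks is lethal to a cancer cell. Whether this works as a
therapy for *metastatic* disease hinges on a population-genetic question:
which of the targets found in a primary tumor survive in every metastasis,
given that cancers keep losing chromosomal material as they evolve?

The answer is governed by zygosity. For a mutation carried on `m` of `C_T`
tumor copies in a sample of purity `p` (contaminating normal cells diploid),
the expected variant allele fraction is

```
E[VAF] = p·m / (p·C_T + (1 − p)·2)
```

so heterozygous diploid sites sit at VAF 0.5, haploid and copy-neutral LOH
sites at 1.0, triploid sites at 1/3 or 2/3. Mutations in regions that
underwent loss of heterozygosity (LOH) *before* the lineages diverged
("truncal LOH") are carried by every descendant cell — losing them would
mean losing the only remaining copy of the region — whereas mutations in
regions still heterozygous can be lost whenever a single sample undergoes
LOH later ("private LOH"): a loss rate of about 50% per copy (50% of sites
when a diploid region goes haploid, 33% when a triploid region loses one of
three copies).

`pamtrace` implements the full analysis:

* **discovery** — tumor−normal subtraction on `(chrom, pos, ref, alt)` keys
  with germline quality gates (MQ ≥ 20, depth ≥ 10, AF ≥ 0.05), then a scan
  of each somatic SBS for GG (plus strand) or CC (minus strand) dinucleotide
  gain overlapping the mutated base, with protospacer extraction and a
  high-VAF (≥ 0.95) subset marking candidate LOH regions;
* **zygosity / LOH scope** — per-segment calls from somatic VAF clusters and
  integer copy number, combined across samples into truncal LOH / private
  LOH / retained heterozygosity per region and per chromosome arm;
* **maintenance** — presence calling at a 5% VAF cutoff with a depth gate,
  truncal-set definition (union over primary samples, or inferred from
  metastases when no primary exists), percent truncal per metastasis,
  percent maintained per PAM, shared-by-all fractions, set overlaps,
  depth/percent-truncal sample QC, and rank-sum / Kruskal–Wallis / ANOVA
  group comparisons;
* **simulation** — a star phylogeny from the cancer-initiating cell with
  trunk and private SBS on explicit homologs, truncal and private LOH
  (copy-loss and copy-neutral), gains, purity dilution, and Poisson/binomial
  read sampling, emitting FASTA + VCF + segment tables plus a truth
  manifest.

## Worked example

`examples/` contains one narrative script per capability. The full pipeline
on the bundled four-sample scenario (one chromosome under truncal copy-loss
LOH, one under private LOH in sample T1, one untouched; 60× depth):

```
$ python examples/04_full_pipeline.py
case A38LIKE: truncal set of 97 PAMs (primary_union)
  T1: percent truncal 83.5%
  T2: percent truncal 100.0%
  T3: percent truncal 100.0%
shared by all lesions: 83.5%

maintenance by LOH class (mean per-PAM percent maintained):
   loh_class  n_pams  mean_percent_maintained
 truncal_loh      18                 1.000000
 private_loh      40                 0.866667
retained_het      39                 1.000000
```

Reading the numbers: T1 carries 83.5% of the case's truncal PAMs — it lost
a random homolog of the private-LOH chromosome, and with it roughly half of
that chromosome's heterozygous targets (40 truncal PAMs sit there; their
mean per-PAM maintenance over the three metastases is 0.87 ≈ 1 − ½·⅓).
Every PAM in the truncal-LOH class is present in every sample: those sites
are haploid in all lineages, at VAF 1, and cannot be lost without losing
the whole region.

The same stages are scriptable from a shell:

```
pamtrace simulate --scenario a38_like --seed 7 --outdir sim/
pamtrace run --manifest sim/case.yaml --out report/
pamtrace discover --tumor T1.vcf --normal N.vcf --ref ref.fa --out pams.tsv
```

## Layout

```
src/pamtrace/     io, pam, loh, maintenance, simulate, pipeline, cli, plots
src/pamtrace/scenarios/   bundled simulation scenarios (YAML)
examples/         narrative scripts, one per capability
tests/            pytest suite (unit, property and end-to-end tests)
docs/methods.md   model, parameters, design choices, limitations
```
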