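# Methods

## Novel-PAM detection

A substitution creates a novel SpCas9 PAM exactly when a dinucleotide
overlapping the mutated base becomes `GG` in the mutant but was not `GG` in
the germline (plus strand), or likewise `CC` on the forward sequence (a
minus-strand PAM). The `N` of `NGG` is irrelevant to novelty — mutating the
N cannot create a PAM where the GG already existed — but the N base must
exist on the contig, so a GG at the very first position of a sequence is
not reported. Each gained dinucleotide is reported as a separate creation
(an alt `G` between two `G` neighbours creates two; an alt outside
`{G, C}` never creates any), because each is an independently targetable
cut site. The 20-base protospacer is read 5′→3′ on the PAM strand from the
*mutant* sequence; near contig ends it may be shorter and is flagged.

Over the 192 possible (ref, alt, left-neighbour, right-neighbour)
combinations with uniform weights, 42 create a PAM: creation requires
alt = G with a G neighbour or alt = C with a C neighbour, and since
ref ≠ alt the germline dinucleotide can never already be GG/CC there. The
package's raw creation rate on uniform sequence is therefore
42/192 ≈ 22%. Observed yields on real tumor genomes are lower (roughly
10%), because production discovery additionally drops sites by mappability,
repeat content and coverage; those caller-level filters are consumed, not
reimplemented, here — the package exposes the unfiltered combinatorial
rate and applies only the documented quality gates.

Protospacers are recorded but not scored for genome-wide uniqueness;
guide-level specificity is a probe/guide design problem outside this
package's scope.

## Tumor−normal subtraction

Somatic status is decided by exact `(chrom, pos, ref, alt)` key subtraction
— an SBS-only pipeline needs no left-alignment window. Germline variants
must pass quality gates (mapping quality ≥ 20, depth ≥ 10, allele
frequency ≥ 0.05; all configurable) *before* they may subtract: a
low-quality germline call neither rescues a tumor variant nor is trusted.
Indels, MNVs and symbolic alleles are excluded at ingest (counted, not
errored); VAF is always recomputed from allelic depths rather than read
from an AF tag, whose dialects vary across callers.

## The VAF–copy-number–purity model

`expected_vaf(p, C_T, m, C_N=2) = p·m / (p·C_T + (1 − p)·C_N)` with purity
`p ∈ (0, 1]`, tumor total copy number `C_T`, mutation multiplicity
`0 ≤ m ≤ C_T`. It is strictly increasing in `m` and nondecreasing in `p`,
and equals 1 at `m = C_T`, `p = 1`. Purity is an input (default 1.0, the
cell-line setting); no purity/ploidy estimation is attempted — heavily
contaminated samples are instead excluded by sample-level QC.

## Zygosity and LOH scope

Zygosity is called per copy-number segment from the sample's *somatic*
variant VAFs only; no germline-SNP B-allele frequencies are required. A
segment with total CN 1 is hemizygous by definition and is called LOH
(copy-loss) from the copy number alone. A segment with CN ≥ 2 is LOH
(copy-neutral) when at least `loh_fraction` (default 0.6) of its
informative variants sit at the `m = C_T` VAF peak — at purity 1 that
means VAF ≥ 0.95; at lower purity the threshold is the expected peak minus
a depth-aware tolerance (0.1 absolute at depth ≥ 30, otherwise 3 binomial
standard deviations). The 0.6 default is deliberate: a genuinely
heterozygous diploid region at practical depth places essentially no
variants at the 0.95 peak (binomial tail of p = 0.5 at depth 60), while a
copy-neutral-LOH region legitimately mixes its dominant duplicated cluster
at VAF 1 with *post-LOH* passenger mutations at VAF 0.5, so demanding
near-unanimity would systematically misread copy-neutral LOH as
heterozygosity. Fewer than `min_support` (default 3) informative variants
gives an indeterminate call.

Scope classification intersects per-sample calls on the union of segment
breakpoints across samples (each grid region lies within one segment of
every sample): LOH in all determinate samples ⇒ truncal LOH (flagged
`mixed_mode` when copy-loss and copy-neutral disagree but all agree on
LOH); in some ⇒ private LOH; in none ⇒ retained heterozygosity.
Indeterminate calls leave the denominator. Arm-level aggregation reports,
per chromosome arm and sample, the mean truncal-PAM VAF, the
length-weighted mean CN, and the fraction of truncal PAMs present.

## Presence calling and maintenance statistics

A site in a sample is `present` when VAF ≥ 5% (inclusive; the cutoff sits
just above background artifact noise in deep capture data), `absent` below,
and `no_call` when total depth < 20 reads (a depth at which a 5% allele is
still detectable with high probability). No-call entries leave both
numerator and denominator of every statistic; this per-site gate
complements the paper-style *sample-level* exclusion and prevents shallow
sites from masquerading as losses.

Truncal PAMs are the union of PAMs present in any primary-tumor sample,
restricted to the capture panel — which derives from metastasis WGS, so
PAMs private to one primary section are not scorable and are excluded.
When no primary exists, truncal is inferred as presence in at least two
metastases. Percent truncal (per metastasis), percent maintained (per
PAM over metastases), shared-by-all, and exact 2ⁿ−1 set-overlap counts
follow the standard multi-region definitions; when nothing is no-call the
mean over PAMs of percent maintained equals the mean over metastases of
percent truncal (both equal the filled-cell fraction of the matrix).

Sample QC formalizes the "linear portion" criterion of percent-truncal vs
mean depth plots as a continuous two-segment least-squares fit: a knee is
accepted only when depths genuinely spread (max ≥ 1.5× min), the split
clearly beats a single line (≤ half the SSE), and the shallow limb both
rises and sits lower; samples below max(30×, knee) are excluded. With
fewer than three samples or a degenerate fit only the hard floor applies.
Group comparisons use the two-sided Mann–Whitney rank-sum test for two
groups (exact method for pooled n ≤ 20, so tiny comparisons match exact
permutation enumeration) and Kruskal–Wallis plus one-way ANOVA for three
or more; p-values are raw, and the absence of multiple-testing correction
is flagged in the output.

## The simulator

The generative model is a star phylogeny rooted at the cancer-initiating
cell over an i.i.d. reference genome at configurable GC content (default
0.41, the human genome-wide value):

1. trunk-level **gains** set the ancestral karyotype with *distinct*
   physical-copy labels, so later mutations in a triploid region land on
   one of three copies with multiplicity 1;
2. **trunk mutations** are placed uniformly at distinct positions, alt
   alleles drawn from a 12-class spectrum (default transition:transversion
   2:1), each assigned one local copy uniformly;
3. truncal **LOH** (copy-loss or copy-neutral) applies on the trunk, before
   divergence: trunk mutations on the lost homolog vanish from every
   sample, and copy-neutral survivors acquire multiplicity 2;
4. each sample then independently receives its **private** CN events (the
   lost copy chosen uniformly at random — this choice, not a fitted
   parameter, produces the 50% diploid and 33% triploid loss rates) and
   private mutations (multiplicity 1, absent from all other samples);
5. **read sampling**: per site, total depth ~ Poisson(mean depth), alt
   depth ~ Binomial(depth, expected VAF from the model above). Capture
   mode writes pileup records at every panel position, including zero-alt
   records, so presence/absence calling is exercised; whole-genome mode
   writes only carried variants.

Segment files keep breakpoints between adjacent equal-CN segments, as real
segmentation output does after integer rounding — merging them would erase
copy-neutral LOH boundaries, which produce no copy-number change. Region
truth labels derive from the final per-sample homolog states (LOH ⇔ all
surviving copies share one label), not from event coverage: a triploid
region that loses one of three distinct copies remains heterozygous even
though its multiplicity-1 sites are lost at 1/3.

All randomness flows from a single seed; emission uses a dedicated RNG
stream per sample, so outputs are byte-identical across reruns and
independent of emission order. Two scenarios ship with the package:
`a38_like` (four tumor samples at purity 1 and 60× — one truncal-LOH
chromosome, one private-LOH chromosome, one retained-het chromosome) and
`full_case` (eight samples over a 10 Mb genome, including copy-neutral
events, a trunk gain with a later private loss, and an FFPE-like sample at
purity 0.3 / 12× that the QC stage should exclude).

### What the simulator does and does not emulate

It reproduces the statistical structure the analysis depends on — VAF
clusters by copy number and multiplicity, truncal-versus-private event
scoping, purity dilution, depth-limited presence calling. It does **not**
model sequencing error, mapping bias, FFPE deamination artifacts,
subclonal selection, stepwise primary-tumor subclonality or polyclonal
seeding; lineages are independent leaves of a star tree. Mutation
densities in the bundled scenarios are far above human genome-wide somatic
density so that megabase-scale chromosomes carry enough informative sites
per segment — tests passing on simulated data therefore validate the
estimators and their interplay, not caller behaviour on real reads.

## Numerical and interface conventions

Internal coordinates are 0-based half-open everywhere; conversion happens
only at the VCF boundary (1-based). Thresholds are inclusive at the stated
boundary (VAF ≥ 0.95 is high-VAF, VAF ≥ 0.05 is present). Report JSON is
written with sorted keys and no timestamps, so reruns are byte-identical.
Venn-style overlaps are reported as exact per-region counts for 2–7 sets;
no diagram is drawn. Arm and VAF figures are optional (matplotlib) extras
behind a flag.

## Problem sizes

The default test and acceptance runs simulate 2–10 Mb genomes with
600–120,000 trunk mutations per case; loss-rate experiments use at least
10,000 PAM-creating sites so that 3 binomial standard errors stay below
1.5 percentage points. These sizes are the package's chosen desk-scale
study conditions; all estimators are linear-time in sites × samples and
scale to whole-genome inputs.

## Known limitations

* Zygosity from somatic VAFs cannot see copy-neutral LOH that carries no
  pre-LOH somatic variants (nothing sits at the peak to witness it), and
  cannot distinguish a balanced triploid→diploid loss from ordinary
  heterozygosity — consistent with its region labels, but worth knowing.
* Purity is trusted as given; no subclonal cancer-cell-fraction
  deconvolution is attempted.
* Protospacer uniqueness/off-target risk is out of scope.
* The QC knee heuristic assumes percent truncal saturates with depth; a
  case whose samples are uniformly shallow is handled by the hard floor
  only.
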