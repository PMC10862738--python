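"""The VAF / copy-number / purity model and per-segment zygosity calls.

Expected VAF of a mutation on m of C_T tumor copies at purity p is
p*m / (p*C_T + (1-p)*2); zygosity of a segment follows from where its
somatic variants cluster.
"""

from pamtrace import (SegmentRecord, VariantRecord, classify_loh_scope,
                      classify_segment_zygosity, expected_vaf)

print("expected VAF by (purity, total CN, multiplicity):")
for p, cn, m in [(1.0, 2, 1), (1.0, 1, 1), (1.0, 2, 2), (1.0, 3, 1),
                 (1.0, 3, 2), (0.5, 2, 1)]:
    print(f"  p={p:.1f}  CN={cn}  m={m}  ->  VAF {expected_vaf(p, cn, m):.3f}")
print("(heterozygous diploid 0.5; haploid or copy-neutral LOH 1.0;"
      " triploid 1/3 and 2/3; purity dilutes)")


def segment(cn, sample):
    return SegmentRecord(chrom="chr1", start=0, end=10_000, total_cn=cn,
                         sample_id=sample)


def variants(vafs, sample):
    return [VariantRecord(chrom="chr1", pos=100 + 7 * i, ref="A", alt="G",
                          sample_id=sample, alt_depth=round(v * 60),
                          total_depth=60)
            for i, v in enumerate(vafs)]


# Four samples over one region: all haploid except S3, which kept both copies.
calls = {}
for sample, cn, vafs in [
    ("S0", 1, [1.0] * 8),
    ("S1", 1, [1.0] * 8),
    ("S2", 1, [1.0] * 8),
    ("S3", 2, [0.5, 0.48, 0.52, 0.5, 0.51, 0.47, 0.53, 0.5]),
]:
    calls[sample] = classify_segment_zygosity(segment(cn, sample),
                                              variants(vafs, sample))
    c = calls[sample]
    print(f"{sample}: CN={cn}  ->  {c.state} ({c.loh_mode}), "
          f"support {c.support}")

scope = classify_loh_scope(("chr1", 0, 10_000), calls)
print(f"cross-sample scope: {scope.scope} "
      f"(LOH in {len(scope.samples_loh)}/{scope.samples_total} samples) — "
      "LOH in some but not all samples means the region is only privately "
      "lost and its PAMs are unsafe targets")
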