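"""Discover somatic PAM-creating substitutions by tumor-normal subtraction.

Builds a toy reference and variant sets in memory, removes germline
variants, and scans each somatic SBS for novel NGG PAM creation.
"""

from pamtrace import (GenomeSequence, VariantRecord, detect_novel_pams,
                      pam_creation_rate, subtract_somatic)

reference = GenomeSequence(
    "chr1",
    "ACGTACGTACGTACGTACGTATGACCTTGAGTTACGTACGTACGTACGTA",
)


def variant(pos, ref, alt, vaf=1.0, depth=60):
    return VariantRecord(chrom="chr1", pos=pos, ref=ref, alt=alt,
                         sample_id="tumor", alt_depth=round(vaf * depth),
                         total_depth=depth)


# Tumor carries three SBS; one is also in the matched normal (germline).
tumor = [
    variant(21, "T", "G"),   # germline ..A T G.. -> A G G : novel PAM
    variant(26, "T", "C"),   # germline ..C C T.. -> C C C : minus-strand PAM
    variant(40, "C", "A"),   # shared with normal, subtracted
]
normal = [VariantRecord(chrom="chr1", pos=40, ref="C", alt="A",
                        sample_id="normal", alt_depth=15, total_depth=30)]

somatic = subtract_somatic(tumor, normal)
print(f"{len(tumor)} tumor variants, {len(somatic)} somatic after subtraction")

for v in somatic:
    for c in detect_novel_pams(v, reference):
        print(f"  {v.chrom}:{v.pos + 1} {v.ref}>{v.alt}  strand {c.strand}  "
              f"PAM window starts at {c.pam_start}  protospacer {c.protospacer}")

rate = pam_creation_rate(somatic, reference)
print(f"creation rate among somatic SBS: {rate:.2f} — the fraction of "
      "substitutions gaining a GG (or CC) overlapping the mutant base; on "
      "uniform random sequence the expectation is 42/192 = 0.22")
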