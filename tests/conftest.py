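import numpy as np
import pytest

from pamtrace.io import GenomeSequence, VariantRecord
from pamtrace.simulate import CnEvent, SampleSpec, SimulationConfig


def make_variant(chrom="chr1", pos=10, ref="A", alt="G", sample="S1",
                 alt_depth=30, total_depth=60) -> VariantRecord:
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         sample_id=sample, alt_depth=alt_depth,
                         total_depth=total_depth)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_reference(rng):
    bases = rng.choice(np.array(list("ACGT")), size=5000)
    return GenomeSequence("chr1", "".join(bases))


@pytest.fixture
def two_sample_config():
    """One primary, one metastasis, whole-chromosome private LOH in the met."""
    return SimulationConfig(
        seed=5,
        n_chromosomes=1,
        chrom_length=200_000,
        n_trunk_mutations=2000,
        n_private_mutations=0,
        samples=[
            SampleSpec("P1", "primary"),
            SampleSpec("M1", "metastasis"),
        ],
        cn_events=[
            CnEvent("chr1", 0, 200_000, "copy_loss", target="M1"),
        ],
    )
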