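import pytest

from hoxloci.core import Genome, GenomicInterval, Peak
from hoxloci.synth import SynthScenario, generate


@pytest.fixture(scope="session")
def toy_genome():
    return Genome((("chrT", 100_000), ("chrU", 80_000)))


@pytest.fixture(scope="session")
def small_dataset():
    """Scaled-down synthetic dataset shared by fast unit tests."""
    return generate(SynthScenario(seed=11).small())


@pytest.fixture(scope="session")
def default_dataset():
    """Study-scale synthetic dataset (the generator's default conditions)."""
    return generate(SynthScenario(seed=5))


def make_peak(chrom, start, end, summit, score=4.0, name="p"):
    return Peak(GenomicInterval(chrom, start, end), summit, score, name)
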