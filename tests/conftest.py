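import numpy as np
import pytest

from divshift import AbundanceVector, CountTable, SampleMetadata


@pytest.fixture
def tiny_table() -> CountTable:
    """2 features x 2 samples with column sums (5, 3)."""
    return CountTable(["f1", "f2"], ["s1", "s2"], np.array([[4, 0], [1, 3]]))


@pytest.fixture
def tiny_metadata() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", "disturbed", "taxonomic"),
        SampleMetadata("s2", "control", "taxonomic"),
    ]


@pytest.fixture
def vec4321() -> AbundanceVector:
    return AbundanceVector.from_counts([4, 3, 2, 1], sample_id="v4321")


def random_vector(rng: np.random.Generator, max_features: int = 30,
                  max_count: int = 50) -> AbundanceVector:
    """A random abundance vector with at least two reads."""
    k = int(rng.integers(2, max_features + 1))
    counts = rng.integers(1, max_count + 1, size=k)
    if counts.sum() < 2:
        counts[0] += 2
    return AbundanceVector.from_counts(counts)
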