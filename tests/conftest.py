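import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=75)
settings.load_profile("ci")

from p1deconv.genome import (
    GenomeMap,
    MarkerInsertion,
    MarkerLibrary,
    load_packaged_library,
)

ECOLI_LENGTH = 4_641_652


@pytest.fixture(scope="session")
def ecoli_genome():
    return GenomeMap("U00096.3", ECOLI_LENGTH, circular=True)


@pytest.fixture(scope="session")
def packaged_library():
    return load_packaged_library()


@pytest.fixture
def toy_genome():
    return GenomeMap("toy", 500_000, circular=True)


@pytest.fixture
def uniform_library(toy_genome):
    """Ten markers every 50 kb on a 500 kb circle; worst distance 25 kb."""
    markers = [
        MarkerInsertion(f"u-{i + 1}", f"strain{i + 1}", 25_000 + 50_000 * i,
                        25_001 + 50_000 * i)
        for i in range(10)
    ]
    return MarkerLibrary(toy_genome, markers)
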