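import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromstates import BinnedGenome, ChromSizes, GenomicInterval

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def sizes():
    return ChromSizes({"chrA": 1000, "chrB": 400})


@pytest.fixture
def grid(sizes):
    return BinnedGenome(sizes, 200)


@pytest.fixture
def rng():
    return np.random.default_rng(20210917)


def random_intervals(rng, sizes, n):
    out = []
    for i in range(n):
        chrom = list(sizes.entries)[rng.integers(len(sizes.entries))]
        length = sizes[chrom]
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, length + 1))
        out.append(GenomicInterval(chrom, start, end, name=f"iv{i}"))
    return out
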