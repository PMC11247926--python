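import numpy as np
import pytest

from chromtrace.panel_design import GenomicInterval, build_codebook, partition_region


def random_sequence(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def toy_panel():
    """Small 10-locus panel (500 kb at 50 kb) with a two-channel codebook."""
    panel = partition_region(GenomicInterval("chrT", 0, 500_000), 50_000)
    return build_codebook(panel)


@pytest.fixture(scope="session")
def full_panel():
    """The 42-locus default-region panel."""
    from chromtrace.panel_design import DEFAULT_REGION

    return build_codebook(partition_region(DEFAULT_REGION, 50_000))
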