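import numpy as np
import pytest

from betasel.io import SiteCount


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_sites(positions, counts, n):
    return [SiteCount(p, c, n) for p, c in zip(positions, counts)]


@pytest.fixture
def toy_contig():
    """3-SNP contig used across scan tests: positions 100/400/600, n=100."""
    return make_sites([100, 400, 600], [50, 50, 25], 100)
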