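import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bsrscan.io_formats import COUNT_COLUMNS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def counts_frame():
    """Small normalized site-count frame spanning two chromosomes."""
    rows = [
        ("chr1", 100, 10, 0, 0, 0, 10, 0, 0, 0),
        ("chr1", 200, 12, 0, 0, 0, 6, 6, 0, 0),
        ("chr1", 300, 0, 12, 0, 0, 11, 0, 0, 0),
        ("chr2", 150, 5, 5, 0, 0, 5, 5, 0, 0),
        ("chr2", 250, 8, 0, 2, 0, 4, 0, 6, 0),
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


@pytest.fixture
def random_profile(rng):
    """Random ED profile over two chromosomes for oracle comparisons."""
    from bsrscan import build_profile

    rows = []
    for chrom, n in (("chr1", 400), ("chr2", 150)):
        pos = np.sort(rng.choice(10_000_000, size=n, replace=False)) + 1
        for p in pos:
            f = rng.multinomial(50, [0.5, 0.5, 0, 0])
            s = rng.multinomial(50, rng.dirichlet([5, 5, 0.2, 0.2]))
            rows.append((chrom, int(p), *f, *s))
    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return build_profile(counts, k=5)
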