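import numpy as np
import pandas as pd
import pytest

from rohscan.core import GenotypeMatrix, from_calls


@pytest.fixture
def tiny_gm() -> GenotypeMatrix:
    """3 individuals x 5 sites, two populations, no optional layers."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1],
            [0, 0, 2, 1, -1],
            [2, 1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return from_calls(
        calls,
        positions=[100, 900, 1100, 5000, 9000],
        populations=["A", "A", "B"],
        individual_ids=["s1", "s2", "s3"],
    )


@pytest.fixture
def hwe_gm():
    """60 individuals x 2000 Hardy-Weinberg sites, one population."""
    rng = np.random.default_rng(7)
    p = rng.uniform(0.1, 0.9, 2000)
    calls = rng.binomial(2, p, size=(60, 2000)).astype(np.int8)
    return from_calls(calls, positions=np.arange(1, 2001) * 500)
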