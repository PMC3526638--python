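import numpy as np
import pandas as pd
import pytest

from seroquant import CountMatrix


@pytest.fixture
def toy_counts() -> CountMatrix:
    """2x2 count matrix used for hand-evaluated enrichment factors."""
    counts = pd.DataFrame(
        [[8, 2], [2, 8]], index=["prot1", "prot2"], columns=["s1", "s2"]
    )
    groups = pd.Series(["N", "AD"], index=["s1", "s2"])
    return CountMatrix(counts=counts, groups=groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120)
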