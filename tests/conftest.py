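import numpy as np
import pandas as pd
import pytest

from spikeflow import CountMatrix


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """Two spikes + three genes over four samples, small fixed counts."""
    counts = pd.DataFrame(
        {
            "s1": [100, 10, 5, 20, 0],
            "s2": [100, 10, 8, 15, 0],
            "s3": [100, 10, 50, 2, 1],
            "s4": [100, 10, 60, 1, 0],
        },
        index=["RNA_SPIKE_1", "RNA_SPIKE_2", "geneA", "geneB", "geneC"],
    )
    is_spike = pd.Series(
        [True, True, False, False, False], index=counts.index, dtype=bool
    )
    return CountMatrix(counts, is_spike)


@pytest.fixture
def tiny_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "donor": ["d1", "d1", "d2", "d2"],
            "sample_type": ["SG", "SG", "EKC", "EKC"],
            "replicate": [1, 2, 1, 2],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
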