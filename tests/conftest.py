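import numpy as np
import pandas as pd
import pytest

from agstates.io import AbundanceTable, join_metadata


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_counts():
    return AbundanceTable(
        pd.DataFrame(
            [[10.0, 30.0], [5.0, 5.0], [0.0, 20.0]],
            index=["s1", "s2", "s3"],
            columns=["tA", "tB"],
        ),
        unit="counts",
    )


@pytest.fixture
def small_meta():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "reactor_id": ["RA", "RA", "RB"],
            "day": [0, 7, 7],
            "wastewater_type": ["simple", "simple", "complex_monomeric"],
            "fraction": ["mixed", "mixed", "flocs"],
        }
    )


@pytest.fixture
def small_dataset(small_counts, small_meta):
    return join_metadata(small_counts, small_meta)
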