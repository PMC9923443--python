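import numpy as np
import pandas as pd
import pytest

from haikal.core_data import FeatureTable
from haikal.synthetic_data import SyntheticConfig, generate


@pytest.fixture
def toy_table() -> FeatureTable:
    """Three decoys, two features, with CAPRI classes."""
    df = pd.DataFrame(
        {
            "target_id": ["t1", "t1", "t2"],
            "decoy_id": ["d1", "d2", "d1"],
            "capri_class": ["M", "I", "A"],
            "f1": [0.1, 0.9, 0.3],
            "f2": [5.0, -2.0, 0.0],
        }
    )
    return FeatureTable(df)


@pytest.fixture(scope="session")
def labeled_table() -> FeatureTable:
    """A mid-sized synthetic decoy table with gold labels (fixed seed)."""
    return generate(
        SyntheticConfig(n_targets=6, decoys_per_target=400, prevalence=0.25, seed=11)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
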