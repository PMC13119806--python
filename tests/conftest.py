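import numpy as np
import pandas as pd
import pytest

from leafstress.config import default_config
from leafstress.synthetic import generate_trait_table


@pytest.fixture(scope="session")
def calibrated_config():
    return default_config(seed=0)


@pytest.fixture(scope="session")
def trait_table(calibrated_config):
    """One seeded draw of the full factorial trait table."""
    return generate_trait_table(calibrated_config)


@pytest.fixture(scope="session")
def wide_traits(trait_table):
    return trait_table.pivot_table(
        index=["treatment", "period", "replicate"], columns="trait", values="value"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture()
def simple_readings():
    """Two leaves with per-leaf a* means 10 and 20, unequal reads per leaf."""
    return pd.DataFrame(
        {
            "leaf_id": [1, 1, 1, 2],
            "reading_index": [1, 2, 3, 1],
            "L_star": [50.0, 50.0, 50.0, 50.0],
            "a_star": [9.0, 10.0, 11.0, 20.0],
            "b_star": [20.0, 20.0, 20.0, 20.0],
        }
    )
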