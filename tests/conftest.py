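import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lemna import synthetic
from lemna.types import OccurrenceMatrix, SiteTable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions: quick to generate, same structure."""
    return synthetic.SynthConfig(n_sites=40, n_taxa=15, group_size=3,
                                 seed=20240101)


@pytest.fixture(scope="session")
def small_survey(small_config):
    return synthetic.generate_survey(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)


@pytest.fixture()
def toy_sites():
    """Five hand-placed sites on one meridian, 0.1 degrees apart."""
    return SiteTable(pd.DataFrame({
        "site_id": [f"s{i}" for i in range(5)],
        "latitude": [41.0, 41.1, 41.2, 41.3, 41.4],
        "longitude": [-72.5] * 5,
        "totalP": [0.01, 0.02, 0.03, 0.04, 0.05],
        "cond": [100.0, 150.0, 200.0, 250.0, 300.0],
    }))


@pytest.fixture()
def toy_occurrence():
    presence = pd.DataFrame(
        {"lemna": [1, 1, 0, 0, 0], "wolffia": [0, 1, 0, 0, 0],
         "elodea": [1, 1, 1, 1, 0]},
        index=pd.Index([f"s{i}" for i in range(5)], name="site_id"))
    return OccurrenceMatrix(presence, {"lemna": "floating",
                                       "wolffia": "floating",
                                       "elodea": "other"})
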