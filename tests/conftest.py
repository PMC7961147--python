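import numpy as np
import pandas as pd
import pytest

from morphomech import synthetic


@pytest.fixture(scope="session")
def default_population() -> pd.DataFrame:
    """Heterogeneous 4-archetype population at the standard study scale."""
    return synthetic.generate_population(n_per_archetype=261, seed=1)


@pytest.fixture(scope="session")
def coupled_table(default_population):
    """Population with YAP assigned under the default coupling (seeded)."""
    table, info = synthetic.assign_yap(default_population, seed=2)
    return table, info


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
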