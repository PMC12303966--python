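import warnings

import numpy as np
import pandas as pd
import pytest

from standnet import synthetic
from standnet.tables import AbundanceTable


@pytest.fixture(scope="session")
def default_design():
    return synthetic.StandDesign(seed=7)


@pytest.fixture(scope="session")
def soil_table(default_design):
    return synthetic.generate_soil_table(default_design)


@pytest.fixture(scope="session")
def abundance_tables(default_design):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.generate_abundance_tables(default_design)


@pytest.fixture
def toy_abundance():
    """5 ASVs x 10 samples with hand-set occupancy and abundance."""
    counts = pd.DataFrame(
        {
            "A1": [50, 60, 55, 40, 45, 52, 58, 49, 51, 50],  # everywhere, abundant
            "A2": [5, 0, 0, 0, 0, 0, 0, 0, 0, 4],  # 2/10 occurrence
            "A3": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],  # everywhere, rare but > 0.01%
            "A4": [0, 0, 0, 0, 0, 0, 0, 0, 0, 3],  # 1/10 occurrence
            "A5": [20, 25, 30, 22, 28, 21, 26, 24, 27, 23],  # everywhere
        },
        index=[f"s{i}" for i in range(10)],
    )
    return AbundanceTable(
        counts=counts,
        taxonomy=pd.Series("k__;p__", index=counts.columns),
        domain="bacteria",
    )
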