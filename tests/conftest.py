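import numpy as np
import pytest

from graminet.core import CountTable, SampleTable
from graminet.simulate import GeneratorConfig, simulate_bundle

SMALL_TAXA = {"archaea": 40, "bacteria": 60, "fungi": 50}


@pytest.fixture(scope="session")
def small_bundle():
    """Default-shaped synthetic bundle at reduced taxon counts."""
    cfg = GeneratorConfig(seed=11, n_taxa=dict(SMALL_TAXA), n_grass_species=24)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def tiny_bundle():
    """One-domain bundle for fast network tests."""
    cfg = GeneratorConfig.link_recovery(5)
    return simulate_bundle(cfg)


@pytest.fixture
def toy_table():
    counts = np.array([[5, 0, 3], [2, 2, 2], [0, 7, 1], [4, 4, 4]])
    return CountTable(["s1", "s2", "s3", "s4"], ["t1", "t2", "t3"], counts, "bacteria")


@pytest.fixture
def toy_frame():
    import pandas as pd

    data = pd.DataFrame(
        {
            "latitude": [33.2, 33.8, 34.4, 35.0],
            "longitude": [98.0, 98.0, 98.0, 98.0],
            "grassland_type": ["ASM", "AM", "AS", "TS"],
            "pH": [7.1, 7.0, 8.0, 8.1],
            "CD": [90.0, 75.0, 55.0, 50.0],
            "S": [10, 12, 7, 5],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleTable(data)
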