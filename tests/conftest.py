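import numpy as np
import pandas as pd
import pytest

import soilnet as sn


@pytest.fixture(scope="session")
def default_dataset():
    """One default-design synthetic dataset (4 sites × 2 treatments × 3
    replicates; 19 ions, 7 enzymes), shared across tests."""
    return sn.generate_dataset(sn.default_config())


@pytest.fixture(scope="session")
def ion_table(default_dataset):
    return default_dataset[0]


@pytest.fixture(scope="session")
def enzyme_table(default_dataset):
    return default_dataset[1]


@pytest.fixture(scope="session")
def metadata(default_dataset):
    return default_dataset[2]


@pytest.fixture(scope="session")
def truth(default_dataset):
    return default_dataset[3]


def make_table(values, category="ion", prefix="v"):
    """Small SampleTable around a raw array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return sn.SampleTable(
        tuple(f"s{i}" for i in range(n)),
        tuple(f"{prefix}{j}" for j in range(p)),
        (category,) * p,
        values,
    )


def make_metadata(sample_ids, sites, fertilizations, replicates=None, ph=None):
    n = len(sample_ids)
    return sn.Metadata(pd.DataFrame({
        "sample_id": list(sample_ids),
        "site": list(sites),
        "fertilization": list(fertilizations),
        "replicate": list(replicates) if replicates is not None else [1] * n,
        "pH": list(ph) if ph is not None else [7.0] * n,
    }))
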