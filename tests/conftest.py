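import numpy as np
import pytest

from pepqsar import dataio


@pytest.fixture(scope="session")
def table():
    return dataio.load_descriptor_table()


@pytest.fixture(scope="session")
def ecoli():
    return dataio.load_ecoli()


@pytest.fixture(scope="session")
def saureus():
    return dataio.load_saureus()


@pytest.fixture(scope="session")
def ecoli_encoded(ecoli, table):
    return dataio.encode_dataset(ecoli, table)


@pytest.fixture(scope="session")
def saureus_encoded(saureus, table):
    return dataio.encode_dataset(saureus, table)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240215)
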