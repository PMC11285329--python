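import pytest
from hypothesis import HealthCheck, settings

from speclean import chem, synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def compound_table():
    return synthetic.load_compound_table()


@pytest.fixture(scope="session")
def compounds(compound_table):
    return {entry.name: entry for entry in compound_table}


@pytest.fixture(scope="session")
def stub_backend():
    return synthetic.stub_backend()


@pytest.fixture(scope="session")
def resolver():
    return synthetic.table_resolver()


@pytest.fixture(scope="session")
def rdkit_backend():
    return chem.default_backend()


@pytest.fixture(scope="session")
def mixed_library():
    """A small dirty library shared by read-only tests."""
    return synthetic.generate_library(200, seed=7)
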