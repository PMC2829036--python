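import pytest

from motifarch.catalog import load_catalog
from motifarch.config import RunConfig


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def srich_members(catalog):
    return catalog.class_union(["ACIDIC", "NEUTRAL_POLAR"])


@pytest.fixture(scope="session")
def dlrich_members(catalog):
    return catalog.class_union(["ACIDIC", "BULKY"])
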