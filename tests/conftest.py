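import numpy as np
import pytest

from pkaqsar.curation import curate_records
from pkaqsar.synthetic import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def fixture_set():
    """A moderate synthetic record set exercising every curation path."""
    return generate_fixture(FixtureSpec(n_structures=80, seed=11))


@pytest.fixture(scope="session")
def curated(fixture_set):
    return curate_records(fixture_set.records)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
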