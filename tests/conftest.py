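import numpy as np
import pytest

from annocompare import fixtures


@pytest.fixture(scope="session")
def taxonomy():
    """Synthetic ranked taxonomy plus handles (chordate subtree, phyla)."""
    return fixtures.synth_taxonomy()


@pytest.fixture()
def worked_example():
    return fixtures.worked_example_dataset()


@pytest.fixture(scope="session")
def ontology():
    return fixtures.synth_ontology()


@pytest.fixture(scope="session")
def habitat_family():
    """Small two-habitat dataset family with truth tables."""
    spec = fixtures.FixtureSpec(seed=11, n_datasets=6, n_records=200)
    return fixtures.synth_datasets(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
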