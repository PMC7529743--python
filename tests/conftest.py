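import pytest

from foodmine.fixtures import FixtureSpec, gen_records_and_snapshots
from foodmine.records import SynonymTable
from foodmine.screening import Vocabulary


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary.load()


@pytest.fixture(scope="session")
def resolver():
    return SynonymTable.from_csv()


@pytest.fixture(scope="session")
def bundle():
    """Default-condition fixture bundle, shared across tests (read-only)."""
    return gen_records_and_snapshots(FixtureSpec(seed=11))


@pytest.fixture()
def small_spec():
    return FixtureSpec(seed=7, n_relevant=10, n_irrelevant=30, n_compounds=20,
                       planted_overlap=(5, 3, 7), n_ref_only=4)
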