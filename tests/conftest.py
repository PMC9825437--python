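import pytest

from varannot.fixture_gen import load_fixture_store, write_fixture_dir
from varannot.scores import compute_apcs

FIXTURE_SEED = 17
FIXTURE_CONTIGS = [("1", 600), ("2", 400)]
FIXTURE_SAMPLES = 30


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    write_fixture_dir(
        out,
        seed=FIXTURE_SEED,
        contigs=FIXTURE_CONTIGS,
        n_samples=FIXTURE_SAMPLES,
    )
    return out


@pytest.fixture(scope="session")
def store_bundle(fixture_dir):
    """(store, registry, gene_model) with aPCs computed, shared by tests
    that do not mutate the store."""
    store, registry, gene_model = load_fixture_store(fixture_dir)
    compute_apcs(store)
    return store, registry, gene_model


@pytest.fixture(scope="session")
def store(store_bundle):
    return store_bundle[0]


@pytest.fixture(scope="session")
def registry(store_bundle):
    return store_bundle[1]


@pytest.fixture(scope="session")
def gene_model(store_bundle):
    return store_bundle[2]
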