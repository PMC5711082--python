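import pytest

from ctdose import (
    FixtureSpec,
    make_cf_tables,
    make_dose_dataset,
    make_scanner,
)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=20140907)


@pytest.fixture(scope="session")
def scanner(spec):
    return make_scanner(spec)


@pytest.fixture(scope="session")
def dataset_and_manifest(spec, scanner):
    return make_dose_dataset(spec, scanner)


@pytest.fixture(scope="session")
def dataset(dataset_and_manifest):
    return dataset_and_manifest[0]


@pytest.fixture(scope="session")
def cf_tables(spec):
    return make_cf_tables(spec)
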