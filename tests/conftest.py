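import pytest

from bivalveseq import build_db, default_assay, write_fixture_refs


@pytest.fixture(scope="session")
def assay():
    return default_assay()


@pytest.fixture(scope="session")
def fixture_db(tmp_path_factory, assay):
    """Two species per family plus the off-target squid record."""
    d = tmp_path_factory.mktemp("refs")
    fasta, tax = write_fixture_refs(d, n_per_family=2, divergence=5, seed=11)
    return build_db(fasta, tax, assay)


@pytest.fixture(scope="session")
def dup_db(tmp_path_factory, assay):
    """Fixture database containing two Pecten species with identical inserts."""
    d = tmp_path_factory.mktemp("refs_dup")
    fasta, tax = write_fixture_refs(
        d, n_per_family=1, divergence=5, seed=11, duplicate_pair=True
    )
    return build_db(fasta, tax, assay)
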