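import pytest

from tagsite import make_fixture, read_query_fasta


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Standard planted-peak bundle: 60 residues, peak at 30."""
    return make_fixture(
        tmp_path_factory.mktemp("bundle"), length=60, peak_position=30, seed=1
    )


@pytest.fixture(scope="session")
def bundle_query(bundle):
    return read_query_fasta(bundle.query_fasta)
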