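import pytest

from ghostseek.db_index import SearchParams, build_chunks
from ghostseek.oracle_fixtures import SyntheticSpec, generate_db, generate_reads


@pytest.fixture(scope="session")
def default_params():
    return SearchParams()


@pytest.fixture(scope="session")
def toy_db():
    """Ten random protein sequences (deterministic)."""
    return generate_db(SyntheticSpec(n_db_seqs=10, db_len_range=(60, 150), seed=42))


@pytest.fixture(scope="session")
def toy_chunks(toy_db, default_params):
    return build_chunks(toy_db, default_params)


@pytest.fixture(scope="session")
def toy_reads(toy_db):
    """Five reads sampled from toy_db at 100% identity, no indels."""
    spec = SyntheticSpec(
        n_db_seqs=10, n_reads=5, target_identity=1.0, indel_rate=0.0, seed=43
    )
    reads, truth = generate_reads(toy_db, spec)
    return reads, truth
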