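import pytest

from cautikit import load_fixtures, load_unaided_rating_table


@pytest.fixture(scope="session")
def fixture_cases():
    return load_fixtures()


@pytest.fixture(scope="session")
def unaided_matrix():
    return load_unaided_rating_table()
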