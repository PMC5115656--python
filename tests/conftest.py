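import pytest

from kynox import paper_fixture


@pytest.fixture(scope="session")
def fixture_tables():
    return paper_fixture()
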