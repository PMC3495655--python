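import pytest

from unismiles import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(0)


@pytest.fixture(scope="session")
def passing_fixtures(fixtures):
    return [r for r in fixtures if r.expected_fail is None]


@pytest.fixture(scope="session")
def base_fixtures(fixtures):
    return [r for r in fixtures if "#" not in r.record_id]
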