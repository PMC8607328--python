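import pytest

from bayes_ssd import load_bundled_summaries


@pytest.fixture(scope="session")
def districts():
    """The thirteen bundled district legacy summaries."""
    return load_bundled_summaries()


@pytest.fixture(scope="session")
def district_by_name(districts):
    return {row.district: row for row in districts}
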