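import pytest

from ndegron import default_table, fragment_panel


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def panel_bundle():
    """Bundled fragment panel: (substrates, sites, families)."""
    return fragment_panel()
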