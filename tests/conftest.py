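import pytest

from chemprofiler import SyntheticSetSpec, fixture_panel, generate_set


@pytest.fixture(scope="session")
def panel():
    """Fixture panel records + independently derived expected-value table."""
    records, expected = fixture_panel()
    return records, expected


@pytest.fixture(scope="session")
def panel_records(panel):
    return panel[0]


@pytest.fixture(scope="session")
def panel_by_id(panel):
    return {r.id: r for r in panel[0]}


@pytest.fixture(scope="session")
def small_synthetic_set():
    """A 60-compound synthetic set shared by curation/stats tests."""
    return generate_set(SyntheticSetSpec(n=60, seed=42))
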