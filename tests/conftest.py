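import pytest

from phytocyanin import classify_family, gen_family_fixture


@pytest.fixture(scope="session")
def rice_fixture():
    """Seeded default family fixture (62 proteins) plus its truth labels."""
    return gen_family_fixture(seed=11)


@pytest.fixture(scope="session")
def rice_assignments(rice_fixture):
    proteins, _ = rice_fixture
    return classify_family(proteins)
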