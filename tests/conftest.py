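import pytest

from nutriscore import default_config, generate_products, load_registry, worked_fixtures


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def fixtures_by_id():
    return {p.id: p for p in worked_fixtures()}


@pytest.fixture(scope="session")
def synthetic_products():
    """Default study conditions: 200 products per category, seed 1."""
    return generate_products(default_config(200), seed=1)


@pytest.fixture(scope="session")
def all_band_tables(registry):
    tables = []
    for spec in registry.specs.values():
        tables.extend(spec.negative.values())
        tables.extend(spec.positive.values())
    return tables
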