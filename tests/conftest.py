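import pytest

from ehrscreen import GeneratorConfig, generate_store, load_demo_templates
from ehrscreen.templates import ConceptRegistry


@pytest.fixture(scope="session")
def demo_templates():
    return load_demo_templates()


@pytest.fixture(scope="session")
def demo_registry(demo_templates):
    """Registry over the demo templates with no derived concepts."""
    return ConceptRegistry.from_templates(demo_templates)


@pytest.fixture(scope="session")
def planted_store():
    """A small seeded store with every benchmark scenario planted."""
    config = GeneratorConfig(
        n_patients=120,
        seed=11,
        plant=[
            ("query1", 4),
            ("query2", 5),
            ("query3", 4),
            ("query4", 3),
            ("query5", 3),
            ("query6", 4),
        ],
    )
    store, truth = generate_store(config)
    return store, truth
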