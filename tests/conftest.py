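import pytest

from lungreport import (
    GeneratorConfig,
    ModelConfig,
    build_default_registry,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def small_cohort(registry):
    """20 well-separated records (delta=3) for quick training checks."""
    return simulate_cohort(GeneratorConfig(n=20, seed=0), registry)


@pytest.fixture(scope="session")
def default_cohort(registry):
    """The paper-default synthetic cohort: 458 records, seed 0."""
    return simulate_cohort(GeneratorConfig(), registry)


@pytest.fixture()
def quick_model_config():
    return ModelConfig(epochs=5)
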