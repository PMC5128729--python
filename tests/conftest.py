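import pytest

from medagg import GeneratorConfig, generate_gentamicin, load_condition_bank
from medagg.experiments import default_capability


@pytest.fixture(scope="session")
def small_dataset():
    """500 seeded neonatal records."""
    return generate_gentamicin(GeneratorConfig(n_records=500, seed=11))


@pytest.fixture(scope="session")
def medium_dataset():
    """2000 seeded neonatal records."""
    return generate_gentamicin(GeneratorConfig(n_records=2000, seed=23))


@pytest.fixture(scope="session")
def condition_bank():
    return load_condition_bank()


@pytest.fixture(scope="session")
def capability():
    return default_capability()
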