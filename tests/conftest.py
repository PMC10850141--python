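import pytest

from copepodamides.chem import enumerate_library
from copepodamides.reference import load_reference
from copepodamides.simdata import default_config, simulate_dataset


@pytest.fixture(scope="session")
def library():
    return enumerate_library()


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small synthetic study with every noise source switched off."""
    from dataclasses import replace

    config = replace(default_config(seed=7).noiseless(), n_individuals_per_site=4)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def default_dataset():
    """Small synthetic study at the default noise settings."""
    from dataclasses import replace

    config = replace(default_config(seed=11), n_individuals_per_site=5)
    return simulate_dataset(config)
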