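import pytest

from mirsense import (
    SensorParameters,
    default_library,
    enumerate_library,
    normalize_to_output_pool,
    simulate_screen,
    summarize_compositions,
)


@pytest.fixture(scope="session")
def basic():
    return SensorParameters.basic()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def compositions(library):
    return enumerate_library(library)


@pytest.fixture(scope="session")
def noiseless_table(library, basic):
    """Noiseless screen: replicates equal the model condition means."""
    return normalize_to_output_pool(
        simulate_screen(library, basic, seed=0, noise_cv=0.0, n_replicates=3)
    )


@pytest.fixture(scope="session")
def noiseless_summaries(noiseless_table):
    return summarize_compositions(noiseless_table)
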