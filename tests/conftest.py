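import warnings

import pytest

from ejcsplice.synthetic import SimConfig, generate_annotation, simulate_event_tables


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=20, seed=7)


@pytest.fixture(scope="session")
def small_world(small_config):
    """A small simulated annotation + genome shared across tests."""
    return generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_events(small_world, small_config):
    annotation, _ = small_world
    return simulate_event_tables(annotation, small_config)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
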