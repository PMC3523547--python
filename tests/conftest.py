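import pytest

from surfscreen import SimulationConfig, generate_dataset, load_reference_tables
from surfscreen.reference import load_packaged_aliases


@pytest.fixture(scope="session")
def reference():
    return load_reference_tables()


@pytest.fixture(scope="session")
def aliases():
    return load_packaged_aliases()


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset shared by read-only tests."""
    config = SimulationConfig(
        n_probes=1500, surface_fraction=0.2, planted_per_disease=25, delta=3.0, seed=1
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two-cohort dataset for fast I/O round trips."""
    config = SimulationConfig(
        n_probes=60,
        cohort_sizes={"EWS": 6, "ARMS": 7},
        surface_fraction=0.3,
        planted_per_disease=5,
        delta=4.0,
        seed=7,
    )
    return generate_dataset(config)
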