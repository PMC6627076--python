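import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from mtburden import (
    BurdenModelConfig,
    SimulationConfig,
    default_config,
    sample_burden,
)


@pytest.fixture(scope="session")
def proliferating_sample():
    """200k-draw reference sample, proliferating cells (SE of a tail ~0.001)."""
    return sample_burden(
        SimulationConfig(model=default_config(True), n_samples=200_000, seed=11)
    )


@pytest.fixture(scope="session")
def non_proliferating_sample():
    return sample_burden(
        SimulationConfig(model=default_config(False), n_samples=200_000, seed=11)
    )


@pytest.fixture()
def degenerate_config():
    """All parameters fixed at their reference means: B is a point mass."""
    from mtburden import fixed

    return BurdenModelConfig(
        copy_number=fixed(1000.0),
        polg_error_rate=fixed(2.94e-7),
        x1=fixed(45.0),
        x2=fixed(280.0),
        x3=fixed(91.0),
    )
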