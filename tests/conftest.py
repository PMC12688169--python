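import numpy as np
import pytest

from ctcgate import (
    SimulationSpec,
    simulate_cartridge,
)


def small_spec(**overrides) -> SimulationSpec:
    """A fast, low-count cartridge spec for unit tests."""
    defaults = dict(
        n_ctc=4,
        n_chc=3,
        n_wbc=20,
        n_debris=4,
        frame_shape=(256, 256),
        n_frames=1,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationSpec(**defaults)


@pytest.fixture(scope="session")
def small_cartridge():
    """One simulated cartridge plus ground truth, shared across tests."""
    return simulate_cartridge(small_spec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
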