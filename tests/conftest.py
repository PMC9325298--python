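import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from micellekin.synthetic import SimConfig, simulate_accretion


@pytest.fixture(scope="session")
def small_event_log():
    """A short two-species accretion run with mutual exit deceleration."""
    cfg = SimConfig(
        species=("SDS", "DDA"),
        counts=(27, 27),
        t_end=300.0,
        seed=11,
        beta_exit=np.array([[0.0, -0.5], [-0.5, 0.0]]),
    )
    return simulate_accretion(cfg)


@pytest.fixture(scope="session")
def pure_event_log():
    """A single-species run (no composition effects), long enough for rates."""
    cfg = SimConfig(species=("SDS",), counts=(54,), k_exit=0.1, t_end=400.0, seed=4)
    return simulate_accretion(cfg)
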