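import numpy as np
import pytest

from clubconv import Panel, SimulationConfig, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20230521)


@pytest.fixture
def random_panel(rng):
    """10 units x 20 years of positive densities with mild heterogeneity."""
    values = np.exp(rng.normal(2.0, 0.5, size=(10, 1)) + rng.normal(0, 0.1, size=(10, 20)))
    return Panel(
        tuple(f"u{i:02d}" for i in range(10)), 2000 + np.arange(20), values
    )


@pytest.fixture
def two_club_config():
    """Two well-separated clubs (limits 2:1) at a scale safe for logs."""
    return SimulationConfig(
        n_units_per_club=(25, 25), club_deltas=(2.0, 1.0), mu_0=10.0, seed=7
    )


@pytest.fixture
def two_club_panel(two_club_config):
    return simulate_panel(two_club_config)
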