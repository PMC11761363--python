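import pytest

from drugscreen import DrugSpec, SimulationConfig


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    """Default study conditions with measurement noise switched off."""
    return SimulationConfig(seed=0, noise_cv=0.0)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def unit_agent_grid_config() -> SimulationConfig:
    """Two identical unit LL.4 agents (b=1, c=0, d=1, e=1 µM), no noise.

    The additive checkerboard built from them has the closed-form surface
    f(a + b) = 1 / (1 + a + b), the canonical sham-combination oracle.
    """
    agent = dict(slope=1.0, floor=0.0, ceiling=1.0, ec50_uM=1.0)
    return SimulationConfig(
        seed=0,
        noise_cv=0.0,
        drugs=(DrugSpec(name="agentA", **agent), DrugSpec(name="agentB", **agent)),
        sensitizer_effect={},
    )
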