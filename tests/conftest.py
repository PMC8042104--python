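"""Shared fixtures: one canonical seeded experiment reused across the suite."""
import pytest

from embryoquant import AbsoluteQuantModel, SimulationConfig, simulate_experiment

#: Canonical fixture seed used by the deterministic frozen-value tests.
FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic experiment (seed 1)."""
    return simulate_experiment(SimulationConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def fitted(default_sim):
    """Calibration fit of the canonical experiment."""
    model = AbsoluteQuantModel(
        default_sim.counts, default_sim.spikes, default_sim.models
    )
    return model.fit()


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast experiment for end-to-end and CLI tests."""
    cfg = SimulationConfig(n_genes=200, depth=2e5, seed=11)
    return simulate_experiment(cfg)
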