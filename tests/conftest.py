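import numpy as np
import pytest

from spheroidrt.config import SimulationConfig, scaled_down_config
from spheroidrt.runner import Simulation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return SimulationConfig()


def tiny_config(**overrides):
    """Very small domain for fast orchestration tests."""
    cfg = scaled_down_config(n_nodes=16, system_size_um=220.0,
                             seeder_ball_radius_um=20.0, total_days=0.1)
    return cfg.replace(**overrides) if overrides else cfg


@pytest.fixture(scope="session")
def grown_sim():
    """Scaled-down spheroid grown until central necrosis has begun.

    Session-scoped: this is the one expensive fixture, shared by the
    growth-ordering, reoxygenation and acceptance tests.
    """
    cfg = scaled_down_config(seed=7)
    sim = Simulation(cfg)
    sim.seed_cells()
    while sim.time_h < 60.0:
        row = sim.step()
        if row["n_necrotic"] >= 20:
            break
    return sim


@pytest.fixture(scope="session")
def dosed_sim(grown_sim):
    """The grown spheroid after a single 4 Gy dose plus 8 h of follow-up."""
    import copy

    from spheroidrt.radiotherapy import DoseEvent, TreatmentSchedule

    sim = copy.deepcopy(grown_sim)
    schedule = TreatmentSchedule((DoseEvent(sim.time_h, 4.0),))
    sim.run(8.0, schedule)
    return sim
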