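import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def duplex8():
    import dnadyn as dd

    return dd.build_duplex(8)


@pytest.fixture(scope="session")
def thermal_duplex():
    """Thermalized 12-bp duplex trajectory, shared across equilibrium tests.

    dt = 0.2 ps keeps the configurational discretization bias of the
    integrator below the percent level for the stiff default table.
    """
    import dnadyn as dd
    from dnadyn.langevin import SimulationProtocol, run_simulation

    s = dd.build_duplex(12)
    proto = SimulationProtocol(
        dt_ps=0.2,
        n_steps=50000,
        friction_update_interval=5000,
        rng_seed=2024,
        output_stride=50,
    )
    traj = run_simulation(s, s.reference_state(), proto)
    burn = traj.n_frames // 5
    return s, traj, burn
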