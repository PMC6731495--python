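import numpy as np
import pytest

import ornsim as o


@pytest.fixture(scope="session")
def kin():
    return o.KineticParams()


@pytest.fixture(scope="session")
def mem():
    return o.MembraneParams()


@pytest.fixture(scope="session")
def thr():
    return o.ThresholdParams()


@pytest.fixture(scope="session")
def pulse_100pg():
    """0.5 s pulse at the 100 pg dose (10 pM = 1e-5 μM), 0.5 s pre/post."""
    return o.pulse_stimulus(0.5, 0.5, 0.5, 1e-5, 1e-5)


@pytest.fixture(scope="session")
def pulse_response_100pg(pulse_100pg):
    """Simulated adaptive-threshold response to the 100 pg pulse."""
    spikes, traces, traj = o.simulate_orn(pulse_100pg, record_traces=True)
    return spikes, traces, traj


def random_states(n, params, seed=0):
    """Random valid kinetic states (complexed fractions included)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        L = rng.uniform(0, 0.5)
        # split receptor pool among free / complexed / active
        w = rng.dirichlet(np.ones(3))
        R, _, Rstar = w * params.R_tot
        N = rng.uniform(0, 1) * params.N_tot
        out.append(o.KineticState(L=L, R=R, Rstar=Rstar, N=N))
    return out
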