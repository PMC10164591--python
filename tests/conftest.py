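import numpy as np
import pytest

import tailkin.types as T
from tailkin.kinetics import simulate


@pytest.fixture(scope="session")
def default_params():
    return T.KineticParams()


@pytest.fixture(scope="session")
def small_basal_ensemble(default_params):
    """A small distributive run on the minimal substrate, reused across tests."""
    sub = T.fam7_a20(conc=50.0)
    grid = np.linspace(0.0, 15 * 60.0, 16)
    return simulate(sub, T.mini_complex(5.0), (), default_params, grid,
                    n_molecules=1000, seed=42)


@pytest.fixture(scope="session")
def burst_ensemble(default_params):
    """A processive burst run (pre-engaged enzymes, Smaug tethering)."""
    sub = T.tce_a70(conc=50.0)
    grid = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0])
    return simulate(sub, T.mini_complex(5.0), (T.smaug(300.0),), default_params,
                    grid, n_molecules=20000, seed=42, pre_bound=True)
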