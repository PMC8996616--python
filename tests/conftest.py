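import numpy as np
import pytest

import memstep as ms


@pytest.fixture(scope="session")
def small_landscape():
    """Six-layer landscape on a 40x40 grid of 0.5 km cells, default windows."""
    ls = ms.default_bear_landscape(seed=7, n_rows=40, n_cols=40,
                                   cell_size=0.5)
    return ls


@pytest.fixture(scope="session")
def null_track():
    p = ms.ParamSet(rho_ns=0.4, kappa=0.5, lambda_=0.4, gamma_=0.75,
                    model="null")
    return ms.simulate_track("null", params=p, n_steps=600, seed=11)


@pytest.fixture(scope="session")
def memory_track():
    """Desk-scale memory-only track: 100-day revisitation cycle at daily
    fixes (one fix per time unit)."""
    p = ms.fig1_regime_params("memory")
    return ms.simulate_track("memory", params=p, n_steps=600, seed=300,
                             training_steps=100, dt=ms.FIG1_DT_HOURS)


@pytest.fixture(scope="session")
def straight_map():
    """Cognitive map of a straight 1 km/step track at 1 h fixes."""
    cm = ms.CognitiveMap(cell_size=0.5, dt_fix=1.0)
    for i in range(21):
        cm.update((float(i), 0.0), float(i))
    return cm


def pytest_configure(config):
    np.seterr(over="ignore")
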