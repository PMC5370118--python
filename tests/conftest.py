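import numpy as np
import pytest

import bgflux as bg


@pytest.fixture(scope="session")
def default_params():
    return bg.CircuitParameters()


@pytest.fixture(scope="session")
def leak_only_params():
    """All couplings removed: seven independent leaky integrators."""
    zero_T = {k: 0.0 for k in bg.CircuitParameters().T}
    return bg.CircuitParameters(T=zero_T, D_input=0.0)


@pytest.fixture(scope="session")
def oscillatory_params():
    return bg.CircuitParameters(D_input=0.8)


@pytest.fixture(scope="session")
def monostable_params():
    return bg.CircuitParameters(D_input=1.4)


@pytest.fixture(scope="session")
def oscillatory_cycle(oscillatory_params):
    cycle = bg.detect_limit_cycle(oscillatory_params)
    assert cycle is not None
    return cycle


@pytest.fixture(scope="session")
def oscillatory_landscape(oscillatory_params):
    """Full pipeline at the reference oscillatory condition (200x200)."""
    return bg.analyze_condition(oscillatory_params, nx=200, ny=200)


@pytest.fixture(scope="session")
def monostable_landscape(monostable_params):
    return bg.analyze_condition(monostable_params, nx=200, ny=200)


@pytest.fixture(scope="session")
def dopamine_scan(default_params):
    """The reference phase-diagram scan: D_input 0.6 .. 1.4, step 0.02."""
    return bg.scan_dopamine(default_params, np.arange(0.6, 1.4001, 0.02))


def unit_circle_cycle(n=10000, r=1.0):
    """Analytic circular 'limit cycle' helper used by several tests."""
    th = np.linspace(0, 2 * np.pi, n)
    y = np.zeros((n, 7))
    y[:, 0] = r * np.cos(th)
    y[:, 5] = r * np.sin(th)
    y[-1] = y[0]
    return bg.LimitCycle(t=np.linspace(0, 100.0, n), y=y, period=100.0)
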