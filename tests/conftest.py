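import numpy as np
import pytest

import silkpop as sp


@pytest.fixture(scope="session")
def plasma_scenario():
    return sp.scenario_from_preset("plasma-like", n_patients=1)


@pytest.fixture(scope="session")
def plasma_series(plasma_scenario):
    """One simulated plasma-like series (12 usable time points, duplicates)."""
    _, extras = sp.simulate_cohort(plasma_scenario, seed=42)
    return extras


@pytest.fixture()
def noiseless_series():
    """Observations lying exactly on a shifted model curve."""
    params = sp.KineticParams(lam=0.05, kc=0.1, shift=0.005)
    times = np.repeat(np.arange(3.0, 36.1, 3.0), 2)
    beta = sp.closed_form_curve(params, times=np.sort(times)).beta
    ria = beta - params.shift
    weights = np.linspace(0.5, 1.5, times.size)
    return params, np.sort(times), ria, weights
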