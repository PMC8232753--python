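import pytest

from multifission.cycle_engine import ScenarioConfig, simulate_culture
from multifission.presets import get_preset


@pytest.fixture(scope="session")
def fig5_500():
    return simulate_culture(get_preset("fig5_500"))


@pytest.fixture(scope="session")
def fig5_250():
    return simulate_culture(get_preset("fig5_250"))


@pytest.fixture(scope="session")
def fig5_110():
    return simulate_culture(get_preset("fig5_110"))


#: incident intensities under which exactly n growth doublings fit into the
#: 18-h light period for n = 1..4
SINGLE_COHORT_LIGHT = {1: 60.0, 2: 110.0, 3: 250.0, 4: 500.0}


@pytest.fixture(scope="session")
def single_cohort_runs():
    """Trajectories with a single cohort completing exactly n sequences."""
    return {
        n: simulate_culture(ScenarioConfig(I_i=I, cohort_fractions={n: 1.0}))
        for n, I in SINGLE_COHORT_LIGHT.items()
    }
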