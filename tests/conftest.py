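import numpy as np
import pytest

import reoxkinetics as rk


@pytest.fixture(scope="session")
def default_schedule():
    """Seven-stage ramp, 70 kg rider: stages at exactly 50/75/100% Wpeak."""
    return rk.build_schedule(1.0, 0.5, 7, 70.0)


@pytest.fixture(scope="session")
def study():
    """One seeded synthetic study under default conditions (21 x 2 x 4)."""
    return rk.simulate_study(rk.PopulationConfig(seed=1))


@pytest.fixture(scope="session")
def study_bouts(study):
    table, accounting = rk.extract_all(study.traces, study.schedules)
    return table, accounting


def make_trace(t, y, site="VL", participant="P01", trial=1, rate_hz=1.0):
    return rk.SmO2Trace(
        t=np.asarray(t, float), y=np.asarray(y, float),
        participant_id=participant, trial=trial, site=site, rate_hz=rate_hz,
    )
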