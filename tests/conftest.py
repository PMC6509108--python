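import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import confdiag as cd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params():
    return cd.ObserverParams(pse_mu=0.0, sigma=6.0, conf_mu=0.0, conf_sigma=5.0,
                             conf_amplitude=0.8, conf_floor=0.05)


@pytest.fixture
def exp1_levels():
    return np.array(cd.EXP1_DESIGN.coherence_levels, dtype=float)


def pseudo_counts(x, p_right, p_low, n=10_000.0):
    """Expected-proportion pseudo-counts: the infinite-data limit of a session."""
    x = np.asarray(x, float)
    n_arr = np.full(len(x), float(n))
    return pd.DataFrame(
        {
            "coherence": x,
            "n_trials": n_arr,
            "n_right": np.asarray(p_right, float) * n_arr,
            "n_low_confidence": np.asarray(p_low, float) * n_arr,
        }
    )


@pytest.fixture
def make_pseudo_counts():
    return pseudo_counts


@pytest.fixture
def baseline_table(params):
    manips = {lab: cd.Manipulation() for lab in cd.EXP1_DESIGN.condition_labels}
    return cd.simulate_experiment(cd.EXP1_DESIGN, params, manips, seed=1234)
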