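import logging

import numpy as np
import pytest

from linkedbar.scenario_sim import sample_profile_indices, scenario_library

# interim refits and Firth fallbacks log routinely during simulation; keep
# test output readable
logging.getLogger("linkedbar").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def library():
    return scenario_library()


@pytest.fixture(scope="session")
def s2_fixture(library):
    """200 patients assigned uniformly across arms under the scenario-2
    truth (T1 doubles response in B1-positive patients)."""
    rng = np.random.default_rng(42)
    s2 = library["S2"]
    n = 200
    profile_idx = sample_profile_indices(s2.prevalence, n, rng)
    arms = rng.integers(0, 4, n)
    table = s2.response_table()
    outcomes = (rng.random(n) < table[arms, profile_idx]).astype(float)
    return arms, profile_idx, outcomes
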