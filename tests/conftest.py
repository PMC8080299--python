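import numpy as np
import pytest

from actibout import synth


@pytest.fixture(scope="session")
def small_pop():
    """A small default-effect population shared across tests (4 wear days
    keeps generation fast while passing the 72-h wear-time QC)."""
    cfg = synth.PopulationConfig(
        n_t2d=25, n_control=50, n_impaired_control=15, days=4, seed=101
    )
    return synth.generate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def quiet_profile():
    """Fully degenerate profile: sleep 23:00-07:00 sharp, no fragmentation,
    no missingness, no between-person variation."""
    prof = synth.default_control_profile(missing_rate=0.0)
    prof.sleep_onset_sd_min = 0.0
    prof.sleep_duration_mean_min = 480.0
    prof.sleep_duration_sd_min = 0.0
    prof.sleep_frag_rate = 0.0
    prof.heterogeneity = synth.Heterogeneity(0.0, 0.0, 0.0, 0.0, 0.0)
    return prof
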