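import numpy as np
import pytest

from qar import scoring, synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_radar():
    return syn.RadarConfig(n_bins=32)


@pytest.fixture
def tiny_cohort_config(small_radar):
    """2 vs 2 subjects, 2-minute sessions: fast end-to-end fixture."""
    return syn.CohortConfig(
        n_adhd=2,
        n_hc=2,
        adhd=syn.adhd_profile(duration_minutes=2.0, changepoint_minute=1.0),
        hc=syn.hc_profile(duration_minutes=2.0, changepoint_minute=1.0),
        radar=small_radar,
        seed=7,
    )


@pytest.fixture
def tiny_cohort(tiny_cohort_config):
    return syn.simulate_cohort(tiny_cohort_config)


@pytest.fixture
def tiny_thresholds(tiny_cohort):
    return scoring.calibrate_threshold(tiny_cohort.empty_room)
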