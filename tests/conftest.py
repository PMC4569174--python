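import pytest

from carekit.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """Full default synthetic dataset (seeded); shared across the session."""
    return simulate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down config for fast end-to-end exercises."""
    return SimConfig(
        seed=11,
        n_focals=12,
        n_focal_females=6,
        n_adult_males=12,
        n_adult_females=12,
        observation_span_days=600,
        n_alive_p1=10,
        n_alive_p2=8,
        measurement_windows=((10, 100), (407, 500), (520, 580)),
        n_lrs_subjects=30,
        n_lrs_females=12,
        n_lrs_dams=12,
        n_lrs_sires=12,
        n_lrs_cohorts=4,
        n_lrs_groups=3,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_all(small_cfg)
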