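import pytest

from digiphen import SimConfig, extract_daily_records, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    # 6 participants x 7 days keeps the full pipeline fast while exercising
    # weekday/weekend schedules and both study arms
    return SimConfig(
        n_intervention=3, n_control=3, n_days=7, seed=42, gps_sample_min=20
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return extract_daily_records(small_cohort)
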