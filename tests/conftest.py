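import pytest

from delaybandit import (
    SHIFT_TYPES,
    ScheduleConfig,
    build_schedule,
    default_group_parameters,
    simulate_agent,
)


@pytest.fixture(scope="session")
def default_config():
    return ScheduleConfig()


@pytest.fixture(scope="session")
def default_schedule(default_config):
    return build_schedule(default_config, SHIFT_TYPES)


@pytest.fixture(scope="session")
def tiny_config():
    """Short schedule for fast fitting/metric tests: 9 sessions x 20 trials."""
    return ScheduleConfig(
        sessions_per_phase=1, initial_baseline_sessions=1, trials_per_session=20
    )


@pytest.fixture(scope="session")
def tiny_schedule(tiny_config):
    return build_schedule(tiny_config, SHIFT_TYPES)


@pytest.fixture(scope="session")
def sham_log(default_schedule):
    """One control-group agent simulated on the full 43-session schedule."""
    model, params = default_group_parameters("sham")
    return simulate_agent(model, params, default_schedule, seed=11,
                          agent_id="sham_demo")
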