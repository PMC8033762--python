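import numpy as np
import pytest

from cardiotrial import registry, run_to_steady_state, simulate
from cardiotrial.protocol import SteadyStateCache, TrialConfig


@pytest.fixture(scope="session")
def fixture_model():
    return registry.create("fixture")


@pytest.fixture(scope="session")
def steady_state_60(fixture_model):
    """Fixture-oscillator state after a 60 s settling run (fast test runs)."""
    state, _ = run_to_steady_state(fixture_model, t_pre=60.0)
    return state


@pytest.fixture(scope="session")
def steady_state_800(fixture_model):
    """State and convergence diagnostic after the full 800 s pre-run."""
    return run_to_steady_state(fixture_model, t_pre=800.0)


@pytest.fixture(scope="session")
def baseline_trace(fixture_model, steady_state_60):
    trace, _ = simulate(fixture_model, 30.0, initial_state=steady_state_60)
    return trace


@pytest.fixture(scope="session")
def trial_cfg():
    """Reduced protocol durations used throughout the test suite."""
    return TrialConfig(t_pre=60.0, t_run=30.0, t_sens=60.0)


@pytest.fixture()
def cache():
    return SteadyStateCache()


@pytest.fixture(scope="session")
def shared_cache():
    return SteadyStateCache()
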