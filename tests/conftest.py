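import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ccdlnm.experiments import make_study
from ccdlnm.pipeline import RunConfig, run_pipeline

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across tests: two years of hourly
    weather at one station, 400 onsets from a known cold-effect surface."""
    records, stations, truth = make_study(seed=42, n_cases=400)
    return records, stations, truth


@pytest.fixture(scope="session")
def fitted(small_study):
    """Temperature-only pipeline fit on the shared study."""
    records, stations, _ = small_study
    config = RunConfig(exposures=("temperature",), adjust_pollutants=False)
    return run_pipeline(config, records, stations)


@pytest.fixture(scope="session")
def variants(small_study):
    """Nine-variant sensitivity refit suite on the shared study."""
    from ccdlnm.effects import run_sensitivity_suite

    records, stations, _ = small_study
    config = RunConfig(exposures=("temperature",), adjust_pollutants=True)
    return run_sensitivity_suite(config, records, stations)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
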