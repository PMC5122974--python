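import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from encortex.cortex import CorticalModel
from encortex.experiments import (ExperimentConfig, ResponseTables,
                                  run_busse, run_full_population,
                                  run_lhi_validation, run_model_comparison)
from encortex.mapsynth import generate_map

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cortical_model() -> CorticalModel:
    return CorticalModel()


@pytest.fixture(scope="session")
def small_map():
    return generate_map(shape=(256, 256), seed=11)


@pytest.fixture(scope="session")
def default_map():
    return generate_map(shape=(512, 512), seed=5)


@pytest.fixture(scope="session")
def model_comparison_report(cortical_model):
    return run_model_comparison(ExperimentConfig(seed=0), cortical_model)


@pytest.fixture(scope="session")
def busse_report(cortical_model):
    return run_busse(ExperimentConfig(seed=0), cortical_model)


@pytest.fixture(scope="session")
def response_tables(cortical_model):
    return ResponseTables(cortical_model)


@pytest.fixture(scope="session")
def population_report(cortical_model, response_tables):
    return run_full_population(ExperimentConfig(seed=7), cortical_model,
                               response_tables)


@pytest.fixture(scope="session")
def lhi_validation_report(default_map):
    return run_lhi_validation(ExperimentConfig(seed=2), omap=default_map)
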