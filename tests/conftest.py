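from dataclasses import replace

import pytest

from stopsig.simulate import (ErpTemplateParams, RaceModelParams,
                              simulate_behavior, simulate_eeg)
from stopsig.task_design import DesignParams, generate_schedule


@pytest.fixture(scope="session")
def small_design() -> DesignParams:
    """60-trial session keeping the 60/40 split and both conditions."""
    return replace(DesignParams(), total_trials=60)


@pytest.fixture(scope="session")
def small_schedule(small_design):
    return generate_schedule(small_design, seed=11)


@pytest.fixture(scope="session")
def small_behavior(small_schedule):
    return simulate_behavior(small_schedule, RaceModelParams(), seed=12)


@pytest.fixture(scope="session")
def clean_templates() -> ErpTemplateParams:
    """Noise-free, artifact-free EEG templates (exact round trips)."""
    return ErpTemplateParams(noise_rms_uv=0.0, blink_rate_per_min=0.0,
                             gross_artifact_p=0.0)


@pytest.fixture(scope="session")
def noiseless_session(small_schedule, small_behavior, clean_templates):
    return simulate_eeg(small_schedule, small_behavior, clean_templates,
                        seed=13)
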