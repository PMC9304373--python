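from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import erpadapt as ea

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def layout128():
    return ea.make_layout(128)


@pytest.fixture(scope="session")
def infant_design_1it():
    return ea.make_design("infant", 1)


@pytest.fixture(scope="session")
def noiseless_config():
    """Validation config with every nuisance source switched off."""
    cfg = ea.normative_config("infant", profile="validation", n_subjects=1)
    return replace(
        cfg,
        pink_rms_uV=0.0,
        line_noise_uV=0.0,
        subject_sd_uV=0.0,
        condition_sd_uV=0.0,
        latency_jitter_sd_ms=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_config, infant_design_1it):
    spec, trials = infant_design_1it
    rec, log = ea.simulate_recording(noiseless_config, spec, trials, seed=7)
    return rec, log


@pytest.fixture(scope="session")
def clean_epochs(noiseless_recording):
    rec, _ = noiseless_recording
    epochs, report = ea.run_preprocessing(rec)
    return ea.assign_conditions(epochs), report


def synthetic_epochset(
    layout,
    n_epochs: int,
    rate_hz: float = 250.0,
    data: np.ndarray | None = None,
    block_type: str = "uniform_human",
    category: str = "human",
):
    """Bare EpochSet on the standard -100..500 ms grid for direct unit tests."""
    times = (np.arange(150) - 25) * 1000.0 / rate_hz
    if data is None:
        data = np.zeros((n_epochs, layout.n_channels, 150))
    labels = pd.DataFrame(
        {
            "category": [category] * n_epochs,
            "block_id": [0] * n_epochs,
            "block_type": [block_type] * n_epochs,
        }
    )
    return ea.EpochSet(
        data=data, times_ms=times, labels=labels, layout=layout, rate_hz=rate_hz
    )
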