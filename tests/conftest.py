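"""Shared fixtures: a reduced-montage study cohort reused across tests.

Study-scale fixtures run the simulator at 16 scalp channels / 128 Hz (the
smallest rate compatible with the 40 Hz band edge and 32 Hz decimation);
the experimental design (8 blocks x 40 trials, 25% targets) is unchanged.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hbci.evaluate import run_pipeline_cv
from hbci.simulate import SimulationConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

STUDY_METHODS = ("majority", "rtci", "nf_bci", "hbci", "confidence_majority")


def study_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Reduced-montage study conditions: 10 participants, 16 ch, 128 Hz."""
    params = dict(
        n_participants=10, n_channels=16, sampling_rate=128.0, seed=seed
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def light_config() -> SimulationConfig:
    return study_config(seed=1)


@pytest.fixture(scope="session")
def cohort(light_config):
    return simulate_cohort(light_config)


@pytest.fixture(scope="session")
def study_run(cohort):
    """Full cross-validated evaluation of the isolated cohort, all methods."""
    return run_pipeline_cv(
        cohort,
        methods=STUDY_METHODS,
        sizes=(1, 2, 3, 4),
        seed=1,
        keep_epochs=True,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
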