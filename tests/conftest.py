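import numpy as np
import pytest

from gaitcoord.synthetic import CohortSpec, ConditionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def condition():
    """A single preferred-speed condition with typical excursions."""
    return ConditionSpec(
        speed_mean=1.07,
        speed_sd=0.21,
        hip_exc_mean=40.5,
        hip_exc_sd=7.6,
        knee_exc_mean=65.2,
        knee_exc_sd=8.6,
        lag_mean_deg=60.0,
        lag_sd_deg=10.0,
        cadence_spm=109.0,
        strides_per_pass=3,
    )


@pytest.fixture
def tiny_cohort_spec(condition):
    """Two participants, one pass per speed, noise-free gyro for exact events."""
    return CohortSpec(
        group="HOA",
        n_participants=2,
        conditions={"preferred": condition},
        passes_per_speed=1,
        fs=200.0,
        gyro_noise_sd=0.0,
        seed=0,
    )
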