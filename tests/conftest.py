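import numpy as np
import pytest

from spikespace.preprocess import RateTensor
from spikespace.synthetic import (
    TaskConfig,
    generate_task_sequence,
    make_default_coupling,
    sample_ensemble_activity,
)


@pytest.fixture(scope="session")
def task_table():
    """Default 160-trial lose-switch task sequence."""
    return generate_task_sequence(TaskConfig())


@pytest.fixture(scope="session")
def default_coupling():
    """Study-condition coupling (predictability-dependent triplets)."""
    return make_default_coupling()


@pytest.fixture(scope="session")
def triplet_coupling():
    """Category-specific triplet supports without predictability effects."""
    return make_default_coupling(predictability_dependence=False)


@pytest.fixture(scope="session")
def small_session(task_table, default_coupling):
    """(spike events, count tensor) for the default 160-trial session."""
    return sample_ensemble_activity(task_table, default_coupling, seed=11, duration_s=1.2)


def random_tensor(n_units=3, n_bins=4, n_trials=24, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, scale, size=(n_units, n_bins, n_trials)) + 5.0
    return RateTensor(
        values=values,
        bin_ms=40.0,
        anchor="poke",
        anchor_times=np.arange(n_trials, dtype=float),
        unit_ids=np.arange(n_units),
        trial_ids=np.arange(n_trials),
    )


@pytest.fixture
def gaussian_tensor():
    return random_tensor()
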