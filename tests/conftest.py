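import numpy as np
import pytest

from neurosrt import (
    SimulatedListener,
    biosemi64_montage,
    make_dataset,
)
from neurosrt.preprocess import preprocess_dataset


@pytest.fixture(scope="session")
def montage():
    return biosemi64_montage()


@pytest.fixture(scope="session")
def small_dataset(montage):
    """A small preprocessed synthetic participant: 4 trials x 6 conditions, 20 s."""
    listener = SimulatedListener(srt_true=-5.0)
    ds = make_dataset(
        listener,
        n_trials_per_condition=4,
        seed=42,
        duration=20.0,
        noise_level=6.0,
        participant_id="fix0",
        montage=montage,
    )
    return preprocess_dataset(ds, montage=montage)


@pytest.fixture(scope="session")
def noise_free_dataset(montage):
    """Noise-free forward simulation: ground-truth recovery fixture."""
    listener = SimulatedListener(srt_true=-5.0)
    return make_dataset(
        listener,
        n_trials_per_condition=8,
        seed=7,
        duration=60.0,
        noise_level=0.0,
        participant_id="nf0",
        montage=montage,
    )
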