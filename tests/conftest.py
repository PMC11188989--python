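import numpy as np
import pandas as pd
import pytest

from megspeech.core_io import EpochSet


def make_epochs(
    data: np.ndarray,
    fs: float = 1000.0,
    t0: float = -0.5,
    participants=None,
    cohorts=None,
    phrases=None,
) -> EpochSet:
    """Wrap a (trials, channels, samples) array in an EpochSet with simple
    metadata, one row per trial."""
    data = np.asarray(data)
    n = data.shape[0]
    trials = pd.DataFrame(
        {
            "participant_id": participants if participants is not None else ["H1"] * n,
            "cohort": cohorts if cohorts is not None else ["healthy"] * n,
            "phrase_id": phrases if phrases is not None else [1] * n,
            "trial_index": np.arange(1, n + 1),
            "valid": True,
        }
    )
    return EpochSet(
        data=data,
        fs=fs,
        t0=t0,
        channel_ids=[f"c{i}" for i in range(data.shape[1])],
        trials=trials,
    )


@pytest.fixture
def epochs_factory():
    return make_epochs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
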