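import numpy as np
import pytest

from eegaffect.io_deap import EEGTrialSet
from eegaffect.synthetic import SynthesisConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Two participants with short trials: fast, still learnable."""
    cfg = SynthesisConfig(
        n_participants=2, n_trials_per_participant=20, n_channels=8,
        n_samples=1024, effect_size=2.0, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture
def canonical_subject(tmp_path):
    """One canonically shaped participant (40 x 40 x 8064) written to npz."""
    rng = np.random.default_rng(0)
    tset = EEGTrialSet(
        signals=rng.standard_normal((40, 40, 8064)).astype(np.float32),
        ratings=rng.uniform(1, 9, size=(40, 4)),
        participant_id="s01",
    )
    return tset


@pytest.fixture
def planted_features():
    """200 x 8 feature matrix with two informative columns (shift 3 sd)."""
    rng = np.random.default_rng(42)
    y = rng.integers(0, 2, 200)
    X = rng.standard_normal((200, 8))
    X[:, 1] += 3.0 * y
    X[:, 5] -= 3.0 * y
    return X, y
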