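import numpy as np
import pytest

from ppgqc import pipeline
from ppgqc.synth import SynthConfig, synth_cohort


@pytest.fixture(scope="session")
def mini_cohort():
    """Small synthetic cohort (4 subjects x 8 min) shared by unit tests."""
    return synth_cohort(SynthConfig(n_subjects=4, duration_s=480.0, seed=11))


@pytest.fixture(scope="session")
def mini_dataset(mini_cohort):
    return pipeline.build_dataset(mini_cohort, per_range=40, seed=11)


@pytest.fixture(scope="session")
def full_cohort():
    """The full-preset cohort (31 subjects, 30 min each)."""
    return synth_cohort(SynthConfig(seed=5))


@pytest.fixture(scope="session")
def full_dataset(full_cohort):
    return pipeline.build_dataset(full_cohort, per_range=100, seed=5)


def make_planted_features(seed: int, n: int = 400, n_noise: int = 16, n_informative: int = 3):
    """Binary-class matrix with planted informative columns followed by
    label-shuffled (uninformative) copies; standardized."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    informative = np.column_stack(
        [y * 1.0 + 0.7 * rng.standard_normal(n) for _ in range(n_informative)]
    )
    noise = np.column_stack(
        [rng.permutation(informative[:, i % n_informative]) for i in range(n_noise)]
    )
    X = np.column_stack([informative, noise])
    return (X - X.mean(0)) / X.std(0), y
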