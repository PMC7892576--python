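import numpy as np
import pytest

from mixclust import MixedDataset, ScenarioSpec, generate_scenario


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One baseline-scenario dataset (N=300, G=6, 4+4 variables, mild)."""
    return generate_scenario(ScenarioSpec(), np.random.default_rng(0))


@pytest.fixture(scope="session")
def easy_dataset():
    """Small, clearly separable mixed dataset: wide continuous gaps, clean
    categorical levels (noise-free)."""
    spec = ScenarioSpec(
        population_size=120,
        n_clusters=3,
        n_continuous=2,
        n_categorical=2,
        sep_index_override=0.5,
        noise_prop_override=0.0,
        label="easy",
    )
    return generate_scenario(spec, np.random.default_rng(1))


def _make_mixed(continuous, categorical, level_counts, labels=None):
    continuous = np.asarray(continuous, dtype=float)
    categorical = np.asarray(categorical, dtype=np.int64)
    if continuous.ndim == 1:
        continuous = continuous[:, None]
    if categorical.ndim == 1:
        categorical = categorical[:, None]
    return MixedDataset(
        continuous=continuous,
        categorical=categorical,
        level_counts=np.asarray(level_counts, dtype=np.int64),
        true_labels=labels,
    )


@pytest.fixture()
def make_mixed():
    """Factory for small hand-built mixed datasets."""
    return _make_mixed
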