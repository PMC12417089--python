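import numpy as np
import pytest

from nfembed import GeneratorConfig, featurize, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """40-strain synthetic dataset under the default study conditions."""
    dataset, truth = generate_dataset(GeneratorConfig(n_samples=40, seed=7))
    return dataset, truth


@pytest.fixture(scope="session")
def small_group_set(small_dataset):
    dataset, _ = small_dataset
    return featurize(dataset.samples)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
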