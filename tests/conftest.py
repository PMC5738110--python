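import numpy as np
import pytest
from hypothesis import settings

from omicsfs import FeatureMatrix, Outcome, SyntheticSpec, make_classification_data

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


def random_matrix(seed: int, n: int, p: int) -> FeatureMatrix:
    rng = np.random.default_rng(seed)
    return FeatureMatrix(rng.standard_normal((n, p)),
                         [f"s{i}" for i in range(n)],
                         [f"f{j}" for j in range(p)])


@pytest.fixture
def tiny_pair():
    """4 samples x 3 features with a clean binary outcome."""
    X = FeatureMatrix(np.arange(12, dtype=float).reshape(4, 3),
                      ["s1", "s2", "s3", "s4"], ["f1", "f2", "f3"])
    y = Outcome("classification", ["A", "A", "B", "B"])
    return X, y


@pytest.fixture(scope="session")
def synth_classification():
    """Small informative/redundant/noise dataset shared across tests."""
    spec = SyntheticSpec(n_samples=100, k_informative=3, k_redundant=4,
                         k_noise=30, effect_size=2.0, redundancy_rho=0.9,
                         seed=11)
    return make_classification_data(spec)
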