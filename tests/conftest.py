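import numpy as np
import pytest

from chemoclass import SpectraConfig, generate_feature_matrix
from chemoclass.synth import PhenotypeConfig, generate_binary_phenotypes


@pytest.fixture(scope="session")
def planted_fm():
    """Default study-structure cohort: 34 vs 74, two planted discriminatory peaks."""
    fm, labels = generate_feature_matrix(SpectraConfig(seed=42))
    return fm, labels


@pytest.fixture(scope="session")
def small_planted_fm():
    """A small balanced planted-effect cohort for quick model tests."""
    fm, labels = generate_feature_matrix(SpectraConfig(n_per_class=(20, 20), seed=7))
    return fm, labels


@pytest.fixture(scope="session")
def phenotypes():
    """Default 41 x 36 binary matrix with latent 6/14/21 clusters."""
    return generate_binary_phenotypes(PhenotypeConfig(seed=3))


def random_two_class(rng, n0=6, n1=8, p=5, effect=0.0):
    """A small random two-class instance for oracle tests."""
    X = rng.normal(size=(n0 + n1, p))
    y = np.array([0] * n0 + [1] * n1)
    X[y == 1, 0] += effect
    return X, y
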