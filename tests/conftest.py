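import numpy as np
import pytest

from isoniche import SpeciesSpec, generate_community, group_by_species


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_community():
    """Three well-separated species with known covariances, n = 200 each."""
    specs = [
        SpeciesSpec("A", mean=(-20.0, 10.0), covariance=np.array([[1.0, 0.3], [0.3, 2.0]]), n=200),
        SpeciesSpec("B", mean=(-16.0, 6.0), covariance=np.array([[2.0, -0.5], [-0.5, 1.5]]), n=200),
        SpeciesSpec("C", mean=(-18.0, 13.0), covariance=np.array([[0.5, 0.0], [0.0, 0.8]]), n=200),
    ]
    df = generate_community(specs, seed=42)
    return specs, df, group_by_species(df)


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
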