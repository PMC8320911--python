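import numpy as np
import pytest

from rdetree import HierarchicalDensityIndex, gaussian_mixture_features


@pytest.fixture(scope="session")
def small_mixture():
    """5 well-separated classes, 12 items each, 8-D."""
    return gaussian_mixture_features(C=5, M=12, K=8, s=6, sigma=1.0, seed=42)


@pytest.fixture(scope="session")
def leaf_corpus():
    """Corpus shaped like a 44-species leaf collection: 44 x 52 items, 64-D,
    well-separated (s=6)."""
    return gaussian_mixture_features(C=44, M=52, K=64, s=6, sigma=1.0, seed=123)


@pytest.fixture(scope="session")
def leaf_index(leaf_corpus):
    """Two-layer index [44, 10] over the leaf-shaped corpus."""
    return HierarchicalDensityIndex(layer_sizes=[44, 10],
                                    random_state=0).fit(leaf_corpus.features)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
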