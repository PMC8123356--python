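import numpy as np
import pytest

from lba.ranking import ComparatorHyperparams, FeatureVector, PreferencePair, train_comparator
from lba.ranking import random_comparator


@pytest.fixture(scope="session")
def planted_utility():
    """A fixed linear utility over 12 features, used to label pairs."""
    rng = np.random.default_rng(123)
    return rng.normal(size=12)


def make_planted_pairs(w, n, seed, schema="planted"):
    rng = np.random.default_rng(seed)
    d = len(w)
    X = rng.normal(size=(n, d))
    Y = rng.normal(size=(n, d))
    out = []
    for x, y in zip(X, Y):
        p, q = (x, y) if w @ x >= w @ y else (y, x)
        out.append(PreferencePair(FeatureVector(p, schema), FeatureVector(q, schema)))
    return out


@pytest.fixture(scope="session")
def small_trained_comparator(planted_utility):
    """A quickly trained comparator for plumbing tests (not accuracy)."""
    pairs = make_planted_pairs(planted_utility, 300, 11)
    return train_comparator(pairs, ComparatorHyperparams(epochs=30), seed=3)


@pytest.fixture(scope="session")
def untrained_comparator():
    return random_comparator("planted", 12, seed=99)
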