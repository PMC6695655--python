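import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from srdeval.classifiers import _aligned_proba
from srdeval.metrics import ScoredPredictions
from srdeval.synthetic import DatasetSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_predictions(rng, n=60, k=2):
    probs = rng.dirichlet(np.ones(k), size=n)
    labels = rng.integers(1, k + 1, size=n)
    return ScoredPredictions(probs, labels)


def random_confusion(rng, positive_floor=1):
    """Random 2x2 counts with at least one actual positive and negative."""
    tp, fn, fp, tn = rng.integers(0, 40, size=4)
    tp += positive_floor
    tn += positive_floor
    return int(tp), int(fn), int(fp), int(tn)


def small_dataset(seed, separation=1.0, counts=((40, 40), (20, 20)), n_features=8):
    spec = DatasetSpec(
        class_counts_train=counts[0],
        class_counts_test=counts[1],
        n_features=n_features,
        separation=separation,
        n_duplicate_features=0,
        n_constant_features=0,
        seed=seed,
    )
    return generate_dataset(spec)


class LabelShufflingWrapper(ClassifierMixin, BaseEstimator):
    """Deliberately crippled model: fits its base estimator on shuffled labels."""

    def __init__(self, base, random_state=0):
        self.base = base
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        shuffled = np.random.default_rng(self.random_state).permutation(y)
        self.model_ = clone(self.base).fit(X, shuffled)
        return self

    def predict_proba(self, X):
        return _aligned_proba(self.model_, X, self.classes_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
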