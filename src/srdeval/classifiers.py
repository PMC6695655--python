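"""The 11-algorithm classifier suite.

Every member is a scikit-learn-style estimator (``fit`` /
``predict_proba`` / ``predict``, ``get_params``/``set_params``, fitted
attributes with a trailing underscore) emitting class probabilities, so the
suite composes with sklearn pipelines and model selection.

Five algorithms with faithful standard implementations delegate to
scikit-learn (Gaussian naive Bayes, 1-nearest neighbour, RBF-kernel SVM,
bagged trees with 10 rounds, random forest).  The remaining six are WEKA-
era algorithms without a scikit-learn equivalent and are implemented here:

* ``HyperPipesClassifier`` — per-class attribute bounding boxes;
* ``OneRClassifier`` — single-attribute rule with bucket discretization;
* ``MultiBoostABClassifier`` — AdaBoost over decision stumps with wagging
  (Poisson-weight) restarts at subcommittee boundaries;
* ``DecorateClassifier`` — tree ensemble diversified with artificial
  training examples labelled against the current ensemble;
* ``EnsembleSelectionClassifier`` — greedy forward model selection with
  replacement, minimizing hold-out RMSE of averaged probabilities;
* ``CfsFilteredClassifier`` — correlation-based feature subset selection
  (best-first search) in front of a base classifier.

The registry maps the suite's standard abbreviations (NaiB, Fil, lBk, Hip,
Mboo, SVM, OneR, Bag, EnS, Dec, RF) to ready-to-fit estimators.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "HyperPipesClassifier",
    "OneRClassifier",
    "MultiBoostABClassifier",
    "DecorateClassifier",
    "EnsembleSelectionClassifier",
    "CfsFilteredClassifier",
    "cfs_merit",
    "cfs_select",
    "ClassifierSpec",
    "REGISTRY_ABBREVIATIONS",
    "registry_specs",
    "make_classifier",
]


def _checked_fit_inputs(estimator, X, y):
    X, y = check_X_y(X, y, dtype=float)
    estimator.n_features_in_ = X.shape[1]
    classes, y_idx = np.unique(y, return_inverse=True)
    estimator.classes_ = classes
    return X, y, y_idx


class HyperPipesClassifier(ClassifierMixin, BaseEstimator):
    """Per-class attribute bounding boxes ("pipes").

    Fitting records, for every class, the min/max of each attribute over
    that class's training instances.  A query's score for a class is the
    fraction of its attributes falling inside the class's bounds;
    probabilities are the normalized scores (uniform when all scores are
    zero).  Training points always score 1.0 for their own class.
    """

    def fit(self, X, y):
        X, y, _ = _checked_fit_inputs(self, X, y)
        self.bounds_min_ = np.vstack([X[y == c].min(axis=0) for c in self.classes_])
        self.bounds_max_ = np.vstack([X[y == c].max(axis=0) for c in self.classes_])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "bounds_min_")
        X = check_array(X, dtype=float)
        inside = (X[:, None, :] >= self.bounds_min_[None]) & (
            X[:, None, :] <= self.bounds_max_[None]
        )
        scores = inside.mean(axis=2)
        totals = scores.sum(axis=1, keepdims=True)
        uniform = np.full_like(scores, 1.0 / len(self.classes_))
        with np.errstate(invalid="ignore"):
            probs = np.where(totals > 0, scores / np.where(totals > 0, totals, 1), uniform)
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class OneRClassifier(ClassifierMixin, BaseEstimator):
    """One-rule classifier: the single best discretized attribute.

    Each attribute is discretized into buckets holding at least
    ``bucket_size`` training values (bucket boundaries never split tied
    values); each bucket predicts its majority class.  The attribute with
    the smallest training error wins (ties toward the lower column index).
    Probabilities are the class frequencies of the selected bucket.
    """

    def __init__(self, bucket_size: int = 6):
        self.bucket_size = bucket_size

    def _discretize(self, values, y_idx, n_classes):
        order = np.argsort(values, kind="stable")
        v, cls = values[order], y_idx[order]
        n = len(v)
        edges = []       # upper boundary (exclusive midpoint) of each closed bucket
        dists = []       # class-count vector per bucket
        start = 0
        while start < n:
            end = min(start + self.bucket_size, n)
            # never split a tie group across a boundary
            while end < n and v[end] == v[end - 1]:
                end += 1
            if n - end < self.bucket_size and end < n:
                end = n  # too few left for another bucket: absorb the tail
            counts = np.bincount(cls[start:end], minlength=n_classes)
            dists.append(counts)
            if end < n:
                edges.append((v[end - 1] + v[end]) / 2)
            start = end
        return np.asarray(edges), np.vstack(dists)

    def fit(self, X, y):
        X, y, y_idx = _checked_fit_inputs(self, X, y)
        if X.shape[0] < self.bucket_size:
            raise ValueError("need at least bucket_size training samples")
        k = len(self.classes_)
        best = None
        for j in range(X.shape[1]):
            edges, dists = self._discretize(X[:, j], y_idx, k)
            errors = int((dists.sum(axis=1) - dists.max(axis=1)).sum())
            if best is None or errors < best[0]:
                best = (errors, j, edges, dists)
        self.training_error_, self.feature_, self.edges_, self.bucket_counts_ = best
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "feature_")
        X = check_array(X, dtype=float)
        bucket = np.searchsorted(self.edges_, X[:, self.feature_], side="right")
        counts = self.bucket_counts_[bucket].astype(float)
        return counts / counts.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class MultiBoostABClassifier(ClassifierMixin, BaseEstimator):
    """AdaBoost over decision stumps with wagging restarts (MultiBoosting).

    The iteration budget is split across subcommittees; at each
    subcommittee boundary the sample weights are re-drawn from a Poisson(1)
    distribution ("wagging"), decorrelating the boosted runs.  Within a
    subcommittee, multiclass AdaBoost (SAMME) reweighting applies.  A stump
    that cannot beat chance ends its subcommittee early.  Prediction is the
    weighted vote of all stumps, normalized to probabilities.
    """

    def __init__(
        self,
        n_iterations: int = 10,
        n_subcommittees: int = 3,
        weight_threshold: int = 100,
        random_state: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.n_subcommittees = n_subcommittees
        self.weight_threshold = weight_threshold
        self.random_state = random_state

    def _restart_points(self):
        return {
            int(np.ceil(i * self.n_iterations / self.n_subcommittees))
            for i in range(self.n_subcommittees)
        }

    def fit(self, X, y):
        X, y, _ = _checked_fit_inputs(self, X, y)
        rng = np.random.default_rng(self.random_state)
        n, k = X.shape[0], len(self.classes_)
        restarts = self._restart_points()
        weights = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        skip_until_restart = False
        for t in range(self.n_iterations):
            if t in restarts:
                weights = rng.poisson(1.0, size=n).astype(float) + 1e-12
                weights /= weights.sum()
                skip_until_restart = False
            if skip_until_restart:
                continue
            fit_weights = self._trim_weights(weights)
            stump = DecisionTreeClassifier(
                max_depth=1, random_state=int(rng.integers(2**31))
            ).fit(X, y, sample_weight=fit_weights)
            pred = stump.predict(X)
            err = float(weights[pred != y].sum())
            if err >= 1 - 1 / k:  # cannot beat chance: end this subcommittee
                skip_until_restart = True
                continue
            err = max(err, 1e-10)
            alpha = np.log((1 - err) / err) + np.log(k - 1)
            self.estimators_.append(stump)
            self.alphas_.append(alpha)
            weights = weights * np.exp(alpha * (pred != y))
            weights /= weights.sum()
        return self

    def _trim_weights(self, weights):
        """WEKA-style weight trimming: keep the heaviest instances covering
        ``weight_threshold`` percent of the total mass (inert at 100)."""
        if self.weight_threshold >= 100:
            return weights
        order = np.argsort(-weights)
        cum = np.cumsum(weights[order])
        cutoff = np.searchsorted(cum, self.weight_threshold / 100) + 1
        trimmed = np.zeros_like(weights)
        trimmed[order[:cutoff]] = weights[order[:cutoff]]
        return trimmed

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X, dtype=float)
        k = len(self.classes_)
        votes = np.zeros((X.shape[0], k))
        for stump, alpha in zip(self.estimators_, self.alphas_):
            pred = stump.predict(X)
            idx = np.searchsorted(self.classes_, pred)
            votes[np.arange(X.shape[0]), idx] += alpha
        totals = votes.sum(axis=1, keepdims=True)
        uniform = np.full_like(votes, 1.0 / k)
        return np.where(totals > 0, votes / np.where(totals > 0, totals, 1), uniform)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class DecorateClassifier(ClassifierMixin, BaseEstimator):
    """Tree ensemble diversified with artificial training examples.

    Candidate members are trained on the union of the real data and a batch
    of artificial examples whose features are drawn from per-attribute
    Gaussians (training mean/sd; zero-sd attributes stay constant) and
    whose labels are drawn with probability inversely proportional to the
    current ensemble's predicted class probabilities.  A candidate joins
    only if the ensemble's training error does not increase; at most
    ``n_iterations`` members are accepted within ``3 * n_iterations``
    trials.
    """

    def __init__(
        self,
        n_iterations: int = 10,
        artificial_fraction: float = 1.0,
        random_state: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.artificial_fraction = artificial_fraction
        self.random_state = random_state

    def _ensemble_proba(self, members, X):
        k = len(self.classes_)
        out = np.zeros((X.shape[0], k))
        for m in members:
            out += _aligned_proba(m, X, self.classes_)
        return out / len(members)

    def fit(self, X, y):
        X, y, _ = _checked_fit_inputs(self, X, y)
        rng = np.random.default_rng(self.random_state)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        n_art = max(1, int(round(self.artificial_fraction * X.shape[0])))
        k = len(self.classes_)

        def new_tree():
            return DecisionTreeClassifier(random_state=int(rng.integers(2**31)))

        members = [new_tree().fit(X, y)]
        error = float(np.mean(self.classes_[
            np.argmax(self._ensemble_proba(members, X), axis=1)] != y))
        trials = 0
        while len(members) < self.n_iterations and trials < 3 * self.n_iterations:
            trials += 1
            X_art = rng.normal(mu, np.where(sd > 0, sd, 0), size=(n_art, X.shape[1]))
            probs = self._ensemble_proba(members, X_art)
            inv = 1.0 / np.maximum(probs, 1e-12)
            inv /= inv.sum(axis=1, keepdims=True)
            y_art = self.classes_[
                np.array([rng.choice(k, p=row) for row in inv])
            ]
            candidate = new_tree().fit(
                np.vstack([X, X_art]), np.concatenate([y, y_art])
            )
            members.append(candidate)
            new_error = float(np.mean(self.classes_[
                np.argmax(self._ensemble_proba(members, X), axis=1)] != y))
            if new_error > error:
                members.pop()
            else:
                error = new_error
        self.estimators_ = members
        self.training_error_ = error
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X, dtype=float)
        return self._ensemble_proba(self.estimators_, X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _aligned_proba(model, X, classes):
    """predict_proba mapped onto a fixed class vector (missing classes -> 0)."""
    probs = model.predict_proba(X)
    if np.array_equal(model.classes_, classes):
        return probs
    out = np.zeros((X.shape[0], len(classes)))
    idx = np.searchsorted(classes, model.classes_)
    out[:, idx] = probs
    return out


def _default_library(random_state):
    rng = np.random.default_rng(random_state)

    def seed():
        return int(rng.integers(2**31))

    return [
        GaussianNB(),
        KNeighborsClassifier(n_neighbors=1),
        KNeighborsClassifier(n_neighbors=5),
        DecisionTreeClassifier(random_state=seed()),
        DecisionTreeClassifier(max_depth=3, random_state=seed()),
        HyperPipesClassifier(),
        OneRClassifier(),
        BaggingClassifier(
            estimator=DecisionTreeClassifier(), n_estimators=10, random_state=seed()
        ),
        RandomForestClassifier(n_estimators=50, random_state=seed()),
    ]


class EnsembleSelectionClassifier(ClassifierMixin, BaseEstimator):
    """Greedy forward ensemble selection with replacement (RMSE criterion).

    Library models are fitted on a stratified sub-split of the training
    data; forward selection (models may be picked repeatedly) minimizes the
    RMSE between the bag-averaged probability vectors and the one-hot
    labels on the held-out fraction, stopping after ``n_iterations`` steps
    or when no addition improves.  The selected bag is refit on the full
    training data; prediction averages its probabilities (with
    multiplicity).
    """

    def __init__(
        self,
        library=None,
        n_iterations: int = 100,
        holdout_fraction: float = 0.25,
        random_state: int | None = None,
    ):
        self.library = library
        self.n_iterations = n_iterations
        self.holdout_fraction = holdout_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X, y, _ = _checked_fit_inputs(self, X, y)
        library = self.library if self.library is not None else _default_library(self.random_state)
        if len(library) == 0:
            raise ValueError("empty model library")
        X_fit, X_val, y_fit, y_val = train_test_split(
            X, y,
            test_size=self.holdout_fraction,
            stratify=y,
            random_state=(self.random_state or 0) % 2**31,
        )
        fitted = [clone(m).fit(X_fit, y_fit) for m in library]
        k = len(self.classes_)
        onehot = np.zeros((len(y_val), k))
        onehot[np.arange(len(y_val)), np.searchsorted(self.classes_, y_val)] = 1.0
        val_probs = [_aligned_proba(m, X_val, self.classes_) for m in fitted]

        def rmse(avg):
            return float(np.sqrt(np.mean((avg - onehot) ** 2)))

        bag: list[int] = []
        bag_sum = np.zeros_like(onehot)
        current = np.inf
        for _ in range(self.n_iterations):
            best_j, best_rmse = None, current
            for j, probs in enumerate(val_probs):
                candidate = (bag_sum + probs) / (len(bag) + 1)
                r = rmse(candidate)
                if r < best_rmse - 1e-15:
                    best_j, best_rmse = j, r
            if best_j is None:
                break
            bag.append(best_j)
            bag_sum += val_probs[best_j]
            current = best_rmse
        self.selection_rmse_ = current
        self.selected_indices_ = bag
        refit_idx = sorted(set(bag))
        refit = {j: clone(library[j]).fit(X, y) for j in refit_idx}
        self.estimators_ = [refit[j] for j in bag]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X, dtype=float)
        out = np.zeros((X.shape[0], len(self.classes_)))
        for m in self.estimators_:
            out += _aligned_proba(m, X, self.classes_)
        return out / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# CFS feature selection


def cfs_merit(rcf: np.ndarray, rff: np.ndarray, subset: list[int]) -> float:
    """Correlation-based subset merit.

    merit(S) = k * mean|r(feature, class)| /
               sqrt(k + k(k-1) * mean|r(feature, feature)|)
    for the k features in ``subset``; reduces to the single feature-class
    correlation at k = 1.
    """
    k = len(subset)
    if k == 0:
        return 0.0
    mean_rcf = float(np.mean(rcf[subset]))
    if k == 1:
        return mean_rcf
    sub = rff[np.ix_(subset, subset)]
    mean_rff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff)


def _abs_corr(a, b):
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def cfs_select(X: np.ndarray, y: np.ndarray, n_fail: int = 5) -> list[int]:
    """Best-first search over feature subsets by CFS merit.

    Expands the best open subset by single-feature additions; stops after
    ``n_fail`` consecutive expansions without improving the best merit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    d = X.shape[1]
    rcf = np.array([_abs_corr(X[:, j], y) for j in range(d)])
    if np.all(rcf == 0) and np.all(X.std(axis=0) == 0):
        raise ValueError("all features are constant")
    rff = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            rff[i, j] = rff[j, i] = _abs_corr(X[:, i], X[:, j])
    counter = 0
    heap = [(-0.0, counter, frozenset())]
    seen = {frozenset()}
    best_merit, best_subset = 0.0, frozenset()
    fails = 0
    while heap and fails < n_fail:
        neg_merit, _, subset = heapq.heappop(heap)
        improved = False
        for j in range(d):
            if j in subset:
                continue
            child = subset | {j}
            if child in seen:
                continue
            seen.add(child)
            merit = cfs_merit(rcf, rff, sorted(child))
            counter += 1
            heapq.heappush(heap, (-merit, counter, child))
            if merit > best_merit + 1e-12:
                best_merit, best_subset = merit, child
                improved = True
        fails = 0 if improved else fails + 1
    if not best_subset:  # all correlations zero: fall back to the best single
        best_subset = {int(np.argmax(rcf))}
    return sorted(best_subset)


class CfsFilteredClassifier(ClassifierMixin, BaseEstimator):
    """CFS attribute selection (best-first search) in front of a base model.

    The base classifier defaults to an unpruned decision tree.
    """

    def __init__(self, base_estimator=None, n_fail: int = 5,
                 random_state: int | None = None):
        self.base_estimator = base_estimator
        self.n_fail = n_fail
        self.random_state = random_state

    def fit(self, X, y):
        X, y, _ = _checked_fit_inputs(self, X, y)
        self.selected_features_ = cfs_select(X, y, self.n_fail)
        base = (
            clone(self.base_estimator)
            if self.base_estimator is not None
            else DecisionTreeClassifier(random_state=self.random_state)
        )
        self.estimator_ = base.fit(X[:, self.selected_features_], y)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        X = check_array(X, dtype=float)
        return _aligned_proba(self.estimator_, X[:, self.selected_features_], self.classes_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class ClassifierSpec:
    """One registry entry: abbreviation, printed hyperparameters, seed."""

    abbreviation: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


_REGISTRY_PARAMS: dict[str, dict] = {
    "NaiB": {},
    "Fil": {"filter": "CFS subset evaluation, best-first search"},
    "lBk": {"n_neighbors": 1, "metric": "euclidean"},
    "Hip": {},
    "Mboo": {"n_iterations": 10, "n_subcommittees": 3, "weight_threshold": 100},
    "SVM": {"kernel": "rbf"},
    "OneR": {"bucket_size": 6},
    "Bag": {"n_estimators": 10},
    "EnS": {"n_iterations": 100, "error_metric": "RMSE"},
    "Dec": {"n_iterations": 10},
    "RF": {"n_estimators": 100},
}
REGISTRY_ABBREVIATIONS = tuple(_REGISTRY_PARAMS)


def registry_specs(seed: int = 0) -> list[ClassifierSpec]:
    """The full suite: exactly 11 classifier specs."""
    return [ClassifierSpec(abbr, dict(params), seed)
            for abbr, params in _REGISTRY_PARAMS.items()]


def make_classifier(spec: ClassifierSpec | str, seed: int | None = None):
    """Instantiate a suite member from its spec or abbreviation."""
    if isinstance(spec, str):
        spec = ClassifierSpec(spec, dict(_REGISTRY_PARAMS.get(spec, {})), seed or 0)
    abbr, s = spec.abbreviation, spec.seed if seed is None else seed
    if abbr == "NaiB":
        return GaussianNB()
    if abbr == "Fil":
        return CfsFilteredClassifier(random_state=s)
    if abbr == "lBk":
        return KNeighborsClassifier(n_neighbors=1)
    if abbr == "Hip":
        return HyperPipesClassifier()
    if abbr == "Mboo":
        return MultiBoostABClassifier(random_state=s)
    if abbr == "SVM":
        # RBF-kernel SVM with Platt-scaled probabilities (internal CV)
        return CalibratedClassifierCV(SVC(kernel="rbf", random_state=s), ensemble=False)
    if abbr == "OneR":
        return OneRClassifier()
    if abbr == "Bag":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=s),
            n_estimators=10,
            random_state=s,
        )
    if abbr == "EnS":
        return EnsembleSelectionClassifier(random_state=s)
    if abbr == "Dec":
        return DecorateClassifier(random_state=s)
    if abbr == "RF":
        return RandomForestClassifier(random_state=s)
    raise ValueError(f"unknown classifier abbreviation {abbr!r}")
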