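"""Synthetic ordinal-class datasets emulating toxicity-categorized compound tables.

The generator produces train/test feature matrices with the statistical
fingerprints of descriptor tables for GHS-categorized toxicity data:

* ordinal class labels 1..k (1 = most benign category) with per-class
  counts fixed by the caller — presets reproduce the three case-study
  compositions (fathead-minnow LC50, daphnia-magna LC50, oral-rat LD50);
* class-conditional Gaussian features whose means advance along a latent
  toxicity axis: every informative descriptor is an equally noisy proxy of
  the latent class, shifted by ``separation`` within-class standard
  deviations per category step, so adjacent categories are the hardest to
  tell apart;
* highly correlated descriptor pairs (r > 0.997) and near-constant
  descriptors (sd < 0.001), the two pathologies the descriptor-filtering
  stage must remove.

Everything is deterministic given the spec's master seed; child seeds for
each purpose are derived via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DatasetSpec",
    "LabelledDataset",
    "generate_dataset",
    "preset_compositions",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one synthetic dataset.

    ``separation`` is the inter-class mean shift per ordinal step, in units
    of the within-class standard deviation, applied to every informative
    feature.  ``n_duplicate_features`` adds noisy copies of informative
    columns (pairwise r > 0.997); ``n_constant_features`` adds columns with
    sd < 0.001.
    """

    class_counts_train: tuple[int, ...]
    class_counts_test: tuple[int, ...]
    n_features: int = 30
    separation: float = 0.3
    n_duplicate_features: int = 3
    n_constant_features: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_counts_train", tuple(int(c) for c in self.class_counts_train))
        object.__setattr__(self, "class_counts_test", tuple(int(c) for c in self.class_counts_test))
        if len(self.class_counts_train) != len(self.class_counts_test):
            raise ValueError("train and test must have the same class count")
        if len(self.class_counts_train) < 2:
            raise ValueError("need at least two classes")
        if min(self.class_counts_train) < 1 or min(self.class_counts_test) < 1:
            raise ValueError("all class counts must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if self.n_duplicate_features < 0 or self.n_constant_features < 0:
            raise ValueError("feature add-on counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return len(self.class_counts_train)

    @property
    def total_features(self) -> int:
        return self.n_features + self.n_duplicate_features + self.n_constant_features

    def to_config(self) -> dict[str, str]:
        return {
            "class_counts_train": ",".join(map(str, self.class_counts_train)),
            "class_counts_test": ",".join(map(str, self.class_counts_test)),
            "n_features": str(self.n_features),
            "separation": repr(self.separation),
            "n_duplicate_features": str(self.n_duplicate_features),
            "n_constant_features": str(self.n_constant_features),
            "seed": str(self.seed),
        }

    @classmethod
    def from_config(cls, cfg: dict[str, str]) -> "DatasetSpec":
        return cls(
            class_counts_train=tuple(int(c) for c in cfg["class_counts_train"].split(",")),
            class_counts_test=tuple(int(c) for c in cfg["class_counts_test"].split(",")),
            n_features=int(cfg["n_features"]),
            separation=float(cfg["separation"]),
            n_duplicate_features=int(cfg["n_duplicate_features"]),
            n_constant_features=int(cfg["n_constant_features"]),
            seed=int(cfg["seed"]),
        )


@dataclass
class LabelledDataset:
    """Train/test splits with ordinal labels 1..k and shared feature columns."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X_train = np.asarray(self.X_train, dtype=float)
        self.X_test = np.asarray(self.X_test, dtype=float)
        self.y_train = np.asarray(self.y_train, dtype=int)
        self.y_test = np.asarray(self.y_test, dtype=int)
        if self.X_train.shape[1] != self.X_test.shape[1]:
            raise ValueError("train and test must share feature columns")
        if not self.feature_names:
            self.feature_names = [f"f{i + 1}" for i in range(self.X_train.shape[1])]
        labels = np.union1d(self.y_train, self.y_test)
        if labels.min() < 1:
            raise ValueError("labels must be ordinal codes starting at 1")

    @property
    def n_classes(self) -> int:
        return int(max(self.y_train.max(), self.y_test.max()))

    @property
    def classes(self) -> np.ndarray:
        return np.arange(1, self.n_classes + 1)


def _draw_split(rng: np.random.Generator, counts, n_features: int, separation: float):
    blocks, labels = [], []
    for cls, count in enumerate(counts, start=1):
        mean = (cls - 1) * separation
        blocks.append(rng.normal(loc=mean, scale=1.0, size=(count, n_features)))
        labels.append(np.full(count, cls))
    return np.vstack(blocks), np.concatenate(labels)


def generate_dataset(spec: DatasetSpec) -> LabelledDataset:
    """Draw one dataset from a spec; identical output for identical specs."""
    seeds = np.random.SeedSequence(spec.seed).spawn(4)
    rng_train = np.random.default_rng(seeds[0])
    rng_test = np.random.default_rng(seeds[1])
    rng_dup = np.random.default_rng(seeds[2])
    rng_const = np.random.default_rng(seeds[3])

    X_train, y_train = _draw_split(rng_train, spec.class_counts_train, spec.n_features, spec.separation)
    X_test, y_test = _draw_split(rng_test, spec.class_counts_test, spec.n_features, spec.separation)
    names = [f"f{i + 1}" for i in range(spec.n_features)]

    # noisy copies: amplitude 0.045 sd gives expected r ~ 1/sqrt(1.002) ~ 0.999
    dup_tr, dup_te = [], []
    for d in range(spec.n_duplicate_features):
        src = d % spec.n_features
        both = np.concatenate([X_train[:, src], X_test[:, src]])
        eps_scale = 0.045 * both.std()
        dup_tr.append(X_train[:, src] + rng_dup.normal(0, eps_scale, X_train.shape[0]))
        dup_te.append(X_test[:, src] + rng_dup.normal(0, eps_scale, X_test.shape[0]))
        names.append(f"f{src + 1}_dup{d + 1}")
    if dup_tr:
        X_train = np.column_stack([X_train, *dup_tr])
        X_test = np.column_stack([X_test, *dup_te])

    for c in range(spec.n_constant_features):
        level = rng_const.uniform(-1, 1)
        X_train = np.column_stack([X_train, level + rng_const.normal(0, 1e-4, X_train.shape[0])])
        X_test = np.column_stack([X_test, level + rng_const.normal(0, 1e-4, X_test.shape[0])])
        names.append(f"const{c + 1}")

    return LabelledDataset(X_train, y_train, X_test, y_test, names)


# Case-study compositions: per-class train/test counts for the three
# toxicity datasets (4 aquatic GHS categories for datasets 1-2, 6 acute
# oral categories for dataset 3), each in a balanced and an imbalanced
# training variant; the test split is identical within a dataset.
_PRESETS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "dataset1-balanced": ((116, 116, 116, 116), (29, 50, 48, 37)),
    "dataset1-imbalanced": ((116, 166, 213, 164), (29, 50, 48, 37)),
    "dataset2-balanced": ((28, 28, 28, 28), (8, 8, 24, 15)),
    "dataset2-imbalanced": ((48, 65, 58, 84), (8, 8, 24, 15)),
    "dataset3-balanced": ((199, 199, 199, 199, 199, 199), (58, 132, 267, 587, 291, 14)),
    "dataset3-imbalanced": ((199, 557, 1053, 2325, 1178, 619), (58, 132, 267, 587, 291, 14)),
}
PRESET_NAMES = tuple(_PRESETS)


def preset_compositions(name: str, **overrides) -> DatasetSpec:
    """Dataset spec for one case-study preset, e.g. ``dataset1-imbalanced``.

    Keyword overrides (``seed``, ``n_features``, ``separation``, ...) are
    applied on top of the preset composition.
    """
    try:
        train, test = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    spec = DatasetSpec(class_counts_train=train, class_counts_test=test)
    return replace(spec, **overrides) if overrides else spec
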