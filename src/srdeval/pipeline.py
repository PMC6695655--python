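"""End-to-end experiment orchestration.

The full study runs, for every combination of dataset composition
(balanced / imbalanced) and classification type (2-class / multiclass):

1. dataset preparation — descriptor filtering (near-constant and highly
   correlated columns), optional class balancing, extreme-class extraction
   for the 2-class scenarios;
2. model building — stratified cross-validation plus an external-test refit
   for every suite classifier, pooling class-probability predictions;
3. panel evaluation — the 28-metric panel per (classifier, validation
   mode), assembled into an objects-by-methods evaluation matrix
   (22 rows x 28 metric columns per dataset);
4. SRD analyses — the metric analysis on the merged, pretreated
   three-dataset matrix against the consensus (row-mean) reference, and
   the classifier analysis on per-dataset transposed matrices against the
   hypothetical-best (oriented min/max) reference;
5. factorial ANOVA of the cross-validated normalized SRD values.

All artifacts are written as CSV with a run manifest; reruns with the same
master seed reproduce every file byte-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from . import io as sio
from .anova import build_long_table, factorial_anova, marginal_means
from .classifiers import REGISTRY_ABBREVIATIONS, _aligned_proba, make_classifier
from .covat import covat_matrix
from .metrics import PANEL, PANEL_ABBREVIATIONS, ScoredPredictions, evaluate_panel
from .srd import SRDResult, srd_analysis
from .synthetic import DatasetSpec, LabelledDataset, generate_dataset, preset_compositions

__all__ = [
    "filter_descriptors",
    "balance_classes",
    "extract_extreme_classes",
    "run_scenario",
    "assemble_matrix",
    "transpose_matrix",
    "merge_and_pretreat",
    "ExperimentConfig",
    "ExperimentResult",
    "run_full_experiment",
]

logger = logging.getLogger("srdeval")

CORRELATION_LIMIT = 0.997
SD_LIMIT = 0.001


def _derive_seed(master: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and a key path."""
    return int(np.random.SeedSequence([int(master), *map(int, key)]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# dataset preparation


def filter_descriptors(dataset: LabelledDataset) -> LabelledDataset:
    """Drop near-constant (sd < 0.001) and highly correlated (|r| > 0.997) columns.

    Statistics come from the training split; the same columns are dropped
    from the test split.  The correlation filter is greedy in column order:
    a later column is dropped when its absolute Pearson correlation with an
    already retained column exceeds the limit.
    """
    X = dataset.X_train
    sds = X.std(axis=0)
    candidates = [j for j in range(X.shape[1]) if sds[j] >= SD_LIMIT]
    kept: list[int] = []
    for j in candidates:
        drop = False
        for i in kept:
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) > CORRELATION_LIMIT:
                drop = True
                break
        if not drop:
            kept.append(j)
    if not kept:
        raise ValueError("descriptor filtering removed every column")
    return LabelledDataset(
        X_train=X[:, kept],
        y_train=dataset.y_train,
        X_test=dataset.X_test[:, kept],
        y_test=dataset.y_test,
        feature_names=[dataset.feature_names[j] for j in kept],
    )


def balance_classes(dataset: LabelledDataset, seed: int = 0) -> LabelledDataset:
    """Downsample every training class to the smallest class count.

    Sampling is without replacement and deterministic given ``seed``; the
    test split is untouched.
    """
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(dataset.y_train, return_counts=True)
    if counts.min() < 1:
        raise ValueError("empty training class")
    n_keep = int(counts.min())
    keep_rows = []
    for c in classes:
        rows = np.flatnonzero(dataset.y_train == c)
        keep_rows.append(np.sort(rng.choice(rows, size=n_keep, replace=False)))
    keep = np.concatenate(keep_rows)
    return LabelledDataset(
        X_train=dataset.X_train[keep],
        y_train=dataset.y_train[keep],
        X_test=dataset.X_test,
        y_test=dataset.y_test,
        feature_names=list(dataset.feature_names),
    )


def extract_extreme_classes(dataset: LabelledDataset) -> LabelledDataset:
    """Keep only the lowest (non-toxic) and highest (most toxic) ordinal
    classes and relabel them 1 and 2."""
    k = dataset.n_classes
    if k < 3:
        raise ValueError("extreme-class extraction needs k >= 3 classes")

    def _subset(X, y):
        mask = (y == 1) | (y == k)
        return X[mask], np.where(y[mask] == k, 2, 1)

    X_tr, y_tr = _subset(dataset.X_train, dataset.y_train)
    X_te, y_te = _subset(dataset.X_test, dataset.y_test)
    return LabelledDataset(X_tr, y_tr, X_te, y_te, list(dataset.feature_names))


# ---------------------------------------------------------------------------
# model building


def _fit_predict(model, X_fit, y_fit, X_eval, classes):
    return _aligned_proba(clone(model).fit(X_fit, y_fit), X_eval, classes)


def run_scenario(
    dataset: LabelledDataset,
    classifiers=REGISTRY_ABBREVIATIONS,
    cv_folds: int = 5,
    seed: int = 0,
    extra_models: dict | None = None,
) -> dict[tuple[str, str], ScoredPredictions]:
    """Cross-validated and external-test predictions for every classifier.

    Returns ``{(abbreviation, mode): ScoredPredictions}`` with mode ``CV``
    (stratified k-fold predictions pooled over folds, covering every
    training sample once) or ``test`` (refit on the full training split,
    scored on the test split).  ``extra_models`` may inject additional
    fitted-on-demand estimators, e.g. deliberately crippled baselines.
    """
    classes = dataset.classes
    counts = np.bincount(dataset.y_train)[1:]
    if counts.min() < cv_folds:
        raise ValueError("a class has fewer training samples than cv_folds")
    models = {abbr: make_classifier(abbr, _derive_seed(seed, i))
              for i, abbr in enumerate(classifiers)}
    if extra_models:
        models.update(extra_models)
    out: dict[tuple[str, str], ScoredPredictions] = {}
    for j, (abbr, model) in enumerate(models.items()):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=_derive_seed(seed, 1000, j))
        cv_probs = np.zeros((len(dataset.y_train), len(classes)))
        for fit_idx, eval_idx in skf.split(dataset.X_train, dataset.y_train):
            cv_probs[eval_idx] = _fit_predict(
                model, dataset.X_train[fit_idx], dataset.y_train[fit_idx],
                dataset.X_train[eval_idx], classes,
            )
        out[(abbr, "CV")] = ScoredPredictions(cv_probs, dataset.y_train, split="CV")
        test_probs = _fit_predict(
            model, dataset.X_train, dataset.y_train, dataset.X_test, classes
        )
        out[(abbr, "test")] = ScoredPredictions(test_probs, dataset.y_test, split="test")
        logger.info("scenario: fitted %s (CV + test)", abbr)
    return out


def assemble_matrix(
    prediction_sets: dict[tuple[str, str], ScoredPredictions],
    x_percent: float = 5.0,
    alpha: float = 20.0,
) -> pd.DataFrame:
    """Evaluation matrix: one row per (classifier, mode), 28 metric columns.

    Test-validated rows carry a ``T`` suffix on the classifier
    abbreviation; cross-validated rows carry the bare abbreviation.
    """
    if not prediction_sets:
        raise ValueError("no prediction sets")
    rows = {}
    for (abbr, mode), preds in prediction_sets.items():
        label = abbr if mode == "CV" else f"{abbr}T"
        rows[label] = evaluate_panel(preds, x_percent=x_percent, alpha=alpha)
    frame = pd.DataFrame(rows).T
    return frame[PANEL_ABBREVIATIONS]


def transpose_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Metrics-in-rows view for the classifier analysis, plus the row
    orientation vector (True where the row's metric is greater-is-better)."""
    transposed = matrix.T
    orientation = np.array(
        [d.greater_is_better for d in PANEL if d.abbreviation in transposed.index]
    )
    return transposed, orientation


# ---------------------------------------------------------------------------
# merging and pretreatment


def _finite_surrogates(column: np.ndarray) -> np.ndarray:
    """Replace ±inf with finite values just beyond the finite range.

    Rank order within the column is preserved, so every SRD quantity is
    unaffected; only the magnitudes entering consensus fusion and scaling
    become finite.
    """
    finite = column[np.isfinite(column)]
    if finite.size == 0:
        return np.where(column > 0, 1.0, -1.0)
    span = finite.max() - finite.min()
    pad = span if span > 0 else max(abs(finite.max()), 1.0)
    out = column.copy()
    out[np.isposinf(column)] = finite.max() + pad
    out[np.isneginf(column)] = finite.min() - pad
    return out


def merge_and_pretreat(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-dataset evaluation matrices for the joint SRD run.

    Smaller-is-better metric columns are negated so every column reads
    greater-is-better; infinities become finite rank-preserving
    surrogates; each column is scaled to unit Euclidean norm within its
    dataset block; blocks are stacked row-wise under a (dataset, model)
    MultiIndex.
    """
    orientation = {d.abbreviation: d.greater_is_better for d in PANEL}
    blocks = []
    panels = [tuple(m.columns) for m in matrices.values()]
    if len(set(panels)) != 1:
        raise ValueError("matrices carry inconsistent metric panels")
    for name, matrix in matrices.items():
        block = matrix.copy().astype(float)
        for col in block.columns:
            values = block[col].to_numpy(dtype=float)
            if not orientation.get(col, True):
                values = -values
            values = _finite_surrogates(values)
            norm = float(np.sqrt(np.sum(values**2)))
            if norm == 0:
                raise ValueError(f"zero-norm column {col!r} in block {name!r}")
            block[col] = values / norm
        block.index = pd.MultiIndex.from_product([[name], block.index],
                                                 names=["dataset", "model"])
        blocks.append(block)
    return pd.concat(blocks, axis=0)


# ---------------------------------------------------------------------------
# the full experiment


@dataclass
class ExperimentConfig:
    """Knobs for the full study; defaults reproduce the study design
    (three case-study compositions, the 11-classifier suite, fivefold model
    CV, fivefold x 10 SRD CV for the metric analysis, sevenfold x 1 for the
    classifier analysis)."""

    dataset_names: tuple[str, ...] = ("dataset1", "dataset2", "dataset3")
    dataset_specs: dict | None = None  # name -> {"balanced"/"imbalanced": DatasetSpec}
    classifiers: tuple[str, ...] = REGISTRY_ABBREVIATIONS
    seed: int = 0
    n_features: int = 30
    separation: float = 0.3
    n_duplicate_features: int = 3
    n_constant_features: int = 2
    cv_folds: int = 5
    srd_metric_folds: int = 5
    srd_metric_iterations: int = 10
    srd_classifier_folds: int = 7
    srd_classifier_iterations: int = 1
    x_percent: float = 5.0
    alpha: float = 20.0
    crrn_draws: int = 100_000

    def resolve_specs(self) -> dict[str, dict[str, DatasetSpec]]:
        if self.dataset_specs is not None:
            return self.dataset_specs
        out = {}
        for i, name in enumerate(self.dataset_names):
            out[name] = {
                comp: preset_compositions(
                    f"{name}-{comp}",
                    n_features=self.n_features,
                    separation=self.separation,
                    n_duplicate_features=self.n_duplicate_features,
                    n_constant_features=self.n_constant_features,
                    seed=_derive_seed(self.seed, 7, i),
                )
                for comp in ("balanced", "imbalanced")
            }
        return out


@dataclass
class ExperimentResult:
    """All artifacts of one full run, keyed by scenario.

    ``matrices``: (composition, classes, dataset) -> 22x28 evaluation matrix;
    ``metric_srd``: (composition, classes) -> SRDResult on the merged matrix;
    ``classifier_srd``: (composition, classes, dataset) -> SRDResult;
    ``covat``: (composition, classes) -> ordered pairwise SRD matrix;
    ``metric_anova`` / ``classifier_anova``: effects tables;
    plus the matching marginal-mean tables.
    """

    matrices: dict = field(default_factory=dict)
    metric_srd: dict = field(default_factory=dict)
    classifier_srd: dict = field(default_factory=dict)
    covat: dict = field(default_factory=dict)
    metric_anova: pd.DataFrame | None = None
    classifier_anova: pd.DataFrame | None = None
    metric_means: pd.DataFrame | None = None
    classifier_means: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


_SCENARIOS = tuple(
    (comp, cls) for comp in ("balanced", "imbalanced") for cls in ("2class", "multiclass")
)


def _prepare(dataset: LabelledDataset, classes: str) -> LabelledDataset:
    data = filter_descriptors(dataset)
    if classes == "2class":
        data = extract_extreme_classes(data)
    return data


def run_full_experiment(config: ExperimentConfig, output_dir=None) -> ExperimentResult:
    """Run every scenario of the study and (optionally) write all artifacts."""
    specs = config.resolve_specs()
    result = ExperimentResult()
    scen_seed = {s: _derive_seed(config.seed, 11, i) for i, s in enumerate(_SCENARIOS)}

    for comp, cls in _SCENARIOS:
        for d_idx, (name, variants) in enumerate(specs.items()):
            data = _prepare(generate_dataset(variants[comp]), cls)
            preds = run_scenario(
                data, config.classifiers, config.cv_folds,
                seed=_derive_seed(scen_seed[(comp, cls)], d_idx),
            )
            matrix = assemble_matrix(preds, config.x_percent, config.alpha)
            result.matrices[(comp, cls, name)] = matrix
            logger.info("stage=matrix scenario=%s/%s dataset=%s shape=%s",
                        comp, cls, name, matrix.shape)

    # metric analysis: merged matrices, consensus (mean) reference
    metric_cv: dict[tuple[str, str], pd.DataFrame] = {}
    for comp, cls in _SCENARIOS:
        merged = merge_and_pretreat(
            {name: result.matrices[(comp, cls, name)] for name in specs}
        )
        res = srd_analysis(
            merged, reference_rule="mean",
            cv_folds=config.srd_metric_folds,
            cv_iterations=config.srd_metric_iterations,
            crrn_draws=config.crrn_draws,
            seed=_derive_seed(scen_seed[(comp, cls)], 21),
        )
        result.metric_srd[(comp, cls)] = res
        result.covat[(comp, cls)] = covat_matrix(merged)
        metric_cv[(comp, cls)] = pd.DataFrame(res.cv_samples, columns=res.columns)
        logger.info("stage=metric-srd scenario=%s/%s m=%d", comp, cls, res.m)

    # classifier analysis: per-dataset transposed matrices, oriented-best reference
    clf_cv: dict[tuple[str, str], pd.DataFrame] = {}
    for comp, cls in _SCENARIOS:
        per_dataset = []
        for d_idx, name in enumerate(specs):
            transposed, orientation = transpose_matrix(result.matrices[(comp, cls, name)])
            res = srd_analysis(
                transposed, reference_rule="oriented-best",
                row_orientation=orientation,
                cv_folds=config.srd_classifier_folds,
                cv_iterations=config.srd_classifier_iterations,
                crrn_draws=config.crrn_draws,
                seed=_derive_seed(scen_seed[(comp, cls)], 22, d_idx),
            )
            result.classifier_srd[(comp, cls, name)] = res
            samples = pd.DataFrame(res.cv_samples, columns=res.columns)
            # pool the CV and external-test columns of one classifier
            pooled = {}
            for abbr in config.classifiers:
                cols = [c for c in samples.columns if c in (abbr, f"{abbr}T")]
                pooled[abbr] = samples[cols].to_numpy().ravel()
            per_dataset.append(pd.DataFrame(pooled))
            logger.info("stage=classifier-srd scenario=%s/%s dataset=%s", comp, cls, name)
        clf_cv[(comp, cls)] = pd.concat(per_dataset, ignore_index=True)

    metric_table = build_long_table(
        {(c, k): metric_cv[(c, k)] for c, k in _SCENARIOS}, level_name="F3"
    )
    clf_table = build_long_table(
        {(c, k): clf_cv[(c, k)] for c, k in _SCENARIOS}, level_name="F3"
    )
    result.metric_anova = factorial_anova(metric_table)
    result.classifier_anova = factorial_anova(clf_table)
    result.metric_means = marginal_means(metric_table, ["F3"])
    result.classifier_means = marginal_means(clf_table, ["F3", "F1"])
    logger.info("stage=anova done")

    result.manifest = {
        "master_seed": config.seed,
        "datasets": ",".join(specs),
        "classifiers": ",".join(config.classifiers),
        "cv_folds": config.cv_folds,
        "srd_metric_cv": f"{config.srd_metric_folds}x{config.srd_metric_iterations}",
        "srd_classifier_cv": f"{config.srd_classifier_folds}x{config.srd_classifier_iterations}",
        "x_percent": config.x_percent,
        "alpha": config.alpha,
    }
    if output_dir is not None:
        _write_artifacts(result, Path(output_dir))
    return result


def _write_artifacts(result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sio.write_config(result.manifest, out / "manifest.cfg")
    for (comp, cls, name), matrix in result.matrices.items():
        sio.write_matrix(matrix, out / f"matrix_{comp}_{cls}_{name}.csv", index_label="model")
    for (comp, cls), res in result.metric_srd.items():
        sio.write_matrix(res.to_frame().set_index("column"),
                         out / f"srd_metrics_{comp}_{cls}.csv", index_label="metric")
    for (comp, cls, name), res in result.classifier_srd.items():
        sio.write_matrix(res.to_frame().set_index("column"),
                         out / f"srd_classifiers_{comp}_{cls}_{name}.csv", index_label="model")
    for (comp, cls), ordered in result.covat.items():
        sio.write_matrix(ordered, out / f"covat_{comp}_{cls}.csv", index_label="metric")
    sio.write_matrix(result.metric_anova, out / "anova_metrics.csv", index_label="term")
    sio.write_matrix(result.classifier_anova, out / "anova_classifiers.csv", index_label="term")
    result.metric_means.to_csv(out / "means_metrics.csv", index=False)
    result.classifier_means.to_csv(out / "means_classifiers.csv", index=False)
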