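"""The 28-metric classification performance panel.

The panel covers three metric families for 2-class problems:

* **local one-sided** — ratios of two cells of the confusion matrix sharing
  a row or column (TPR/FNR, TNR/FPR, PPV/FDR, NPV/FOR); each pair sums to 1;
* **local two-sided** — functions of more than two cells at one decision
  threshold (ACC, BACC, F1, MCC, BM, MK, LR+, LR-, DOR, EF, ROC_EF, Cohen's
  kappa, Jaccard, Brier score loss, RIE);
* **global** — threshold-free metrics integrating over the score ranking
  (AUC, AUAC, AP, BEDROC, average rank of actives).

Multiclass inputs are handled by the printed multiclass forms where one
exists (ACC, BACC, MCC, kappa, Brier) and by count-weighted one-vs-rest
averaging for everything else: the metric is evaluated k times with class j
as the positive class (scores = predicted probability of class j) and the
k values are averaged with the actual class counts as weights.

Conventions used for degenerate inputs:

* zero denominators in the one-sided rates mark both members of the
  affected complementary pair as NaN;
* LR+, LR- and DOR return signed infinity when only the denominator
  vanishes (infinities still rank correctly in SRD) and NaN for 0/0; an
  optional +0.5 continuity correction is available but off by default;
* MCC and kappa return 0 when their denominators vanish (the
  no-information convention);
* tied scores receive fractional (average) ranks in every ranking-based
  metric, and tie groups at the enrichment-factor cutoff contribute
  fractionally, so all metrics are invariant to sample reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ScoredPredictions",
    "ConfusionMatrix",
    "MetricDescriptor",
    "PANEL",
    "PANEL_ABBREVIATIONS",
    "SMALLER_BETTER",
    "labels_from_probabilities",
    "confusion_matrix",
    "one_sided_rates",
    "composite_local_metrics",
    "brier_score",
    "enrichment_metrics",
    "rie_bedroc",
    "curve_metrics",
    "one_vs_rest_weighted",
    "evaluate_panel",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ScoredPredictions:
    """Class-probability predictions plus ground truth.

    ``probabilities`` is n-by-k (rows sum to 1), ``true_labels`` holds
    ordinal class codes 1..k, and ``positive_class`` names the class used
    as "Actual +" in 2-class metrics (default: the highest code, i.e. the
    most toxic category under the ordinal labelling convention).
    """

    probabilities: np.ndarray
    true_labels: np.ndarray
    positive_class: int | None = None
    split: str = ""

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] < 2:
            raise ValueError("probabilities must be n-by-k with k >= 2")
        if self.probabilities.shape[0] != self.true_labels.shape[0]:
            raise ValueError("probabilities and true_labels disagree on n")
        sums = self.probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("probability rows must sum to 1 (±1e-9)")
        k = self.probabilities.shape[1]
        if self.true_labels.min() < 1 or self.true_labels.max() > k:
            raise ValueError("true labels must be ordinal codes in 1..k")
        if self.positive_class is None:
            self.positive_class = k

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[1]

    @property
    def n_samples(self) -> int:
        return self.probabilities.shape[0]


@dataclass
class ConfusionMatrix:
    """k-by-k count table, rows = actual class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square k-by-k table")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def binary(self, positive_class: int) -> tuple[int, int, int, int]:
        """Collapse to (TP, FN, FP, TN) with ``positive_class`` as Actual +."""
        p = positive_class - 1
        if not 0 <= p < self.k:
            raise ValueError("positive_class outside 1..k")
        tp = int(self.counts[p, p])
        fn = int(self.counts[p].sum() - tp)
        fp = int(self.counts[:, p].sum() - tp)
        tn = self.n - tp - fn - fp
        return tp, fn, fp, tn


@dataclass(frozen=True)
class MetricDescriptor:
    """Panel metadata for one metric."""

    abbreviation: str
    family: str  # local-one-sided | local-two-sided | global
    greater_is_better: bool
    needs_scores: bool = False
    parameters: dict = field(default_factory=dict)


SMALLER_BETTER = frozenset({"FNR", "FPR", "FDR", "FOR", "LR-", "B", "r"})

_ONE_SIDED = ["TPR", "FNR", "TNR", "FPR", "PPV", "FDR", "NPV", "FOR"]
_TWO_SIDED = [
    "ACC", "BACC", "F1", "MCC", "BM", "MK", "LR+", "LR-", "DOR",
    "EF", "ROC_EF", "kappa", "J", "B", "RIE",
]
_GLOBAL = ["AUC", "AUAC", "AP", "BEDROC", "r"]
_NEEDS_SCORES = frozenset({"EF", "ROC_EF", "B", "RIE", "AUC", "AUAC", "AP", "BEDROC", "r"})

PANEL: list[MetricDescriptor] = [
    MetricDescriptor(
        abbreviation=abbr,
        family=fam,
        greater_is_better=abbr not in SMALLER_BETTER,
        needs_scores=abbr in _NEEDS_SCORES,
        parameters=(
            {"x_percent": 5.0} if abbr in ("EF", "ROC_EF")
            else {"alpha": 20.0} if abbr in ("RIE", "BEDROC")
            else {}
        ),
    )
    for abbr, fam in (
        [(a, "local-one-sided") for a in _ONE_SIDED]
        + [(a, "local-two-sided") for a in _TWO_SIDED]
        + [(a, "global") for a in _GLOBAL]
    )
]
PANEL_ABBREVIATIONS = [d.abbreviation for d in PANEL]
assert len(PANEL) == 28


# ---------------------------------------------------------------------------
# label assignment and confusion counts


def labels_from_probabilities(preds: ScoredPredictions) -> np.ndarray:
    """Predicted class codes: argmax per row, ties toward the lowest code."""
    probs = preds.probabilities
    if np.isnan(probs).any():
        raise ValueError("probability rows contain NaN")
    return np.argmax(probs, axis=1) + 1


def confusion_matrix(true_labels, predicted_labels, k: int) -> ConfusionMatrix:
    """Count table of actual (rows) vs predicted (columns) class codes 1..k."""
    true_labels = np.asarray(true_labels, dtype=int)
    predicted_labels = np.asarray(predicted_labels, dtype=int)
    if true_labels.size == 0:
        raise ValueError("empty input")
    for arr in (true_labels, predicted_labels):
        if arr.min() < 1 or arr.max() > k:
            raise ValueError("label outside 1..k")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (true_labels - 1, predicted_labels - 1), 1)
    return ConfusionMatrix(counts)


# ---------------------------------------------------------------------------
# local metrics


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def one_sided_rates(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """The eight one-sided rates; zero denominators mark both pair members NaN."""
    p, n = tp + fn, tn + fp
    pp, pn = tp + fp, tn + fn
    return {
        "TPR": _safe_ratio(tp, p),
        "FNR": _safe_ratio(fn, p),
        "TNR": _safe_ratio(tn, n),
        "FPR": _safe_ratio(fp, n),
        "PPV": _safe_ratio(tp, pp),
        "FDR": _safe_ratio(fp, pp),
        "NPV": _safe_ratio(tn, pn),
        "FOR": _safe_ratio(fn, pn),
    }


def _likelihood_ratio(num: float, den: float) -> float:
    """LR-style ratio: inf when only the denominator vanishes, NaN for 0/0."""
    if math.isnan(num) or math.isnan(den):
        return math.nan
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def composite_local_metrics(
    tp: int, fn: int, fp: int, tn: int, continuity_correction: bool = False
) -> dict[str, float]:
    """Two-sided local metrics from a 2-class confusion matrix.

    ``continuity_correction=True`` adds 0.5 to every cell before computing
    LR+, LR- and DOR (avoids infinities); off by default since infinities
    rank correctly in SRD.
    """
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    rates = one_sided_rates(tp, fn, fp, tn)
    tpr, tnr = rates["TPR"], rates["TNR"]
    ppv, npv = rates["PPV"], rates["NPV"]
    acc = (tp + tn) / n
    bacc = (tpr + tnr) / 2
    f1 = _safe_ratio(2 * tp, 2 * tp + fp + fn)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0
    if continuity_correction:
        ctp, cfn, cfp, ctn = tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5
        ctpr, cfpr = ctp / (ctp + cfn), cfp / (ctn + cfp)
        cfnr, ctnr = cfn / (ctp + cfn), ctn / (ctn + cfp)
        lr_pos, lr_neg = ctpr / cfpr, cfnr / ctnr
        dor = lr_pos / lr_neg
    else:
        lr_pos = _likelihood_ratio(tpr, rates["FPR"])
        lr_neg = _likelihood_ratio(rates["FNR"], tnr)
        dor = _likelihood_ratio(float(tp) * tn, float(fp) * fn)
    baseline = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    kappa = (acc - baseline) / (1 - baseline) if baseline < 1 else 0.0
    return {
        "ACC": acc,
        "BACC": bacc,
        "F1": f1,
        "MCC": mcc,
        "BM": tpr + tnr - 1,
        "MK": ppv + npv - 1,
        "LR+": lr_pos,
        "LR-": lr_neg,
        "DOR": dor,
        "kappa": kappa,
        "J": _safe_ratio(tp, tp + fn + fp),
    }


def _multiclass_composites(cm: ConfusionMatrix) -> dict[str, float]:
    """Printed multiclass forms of ACC, BACC, MCC and kappa."""
    counts = cm.counts.astype(float)
    n = counts.sum()
    n_actual = counts.sum(axis=1)
    n_pred = counts.sum(axis=0)
    n_correct = np.trace(counts)
    acc = n_correct / n
    with np.errstate(invalid="ignore", divide="ignore"):
        recalls = np.diag(counts) / n_actual
    bacc = float(np.nanmean(np.where(n_actual > 0, recalls, np.nan)))
    mcc_den = math.sqrt((n**2 - (n_pred**2).sum()) * (n**2 - (n_actual**2).sum()))
    mcc = (n_correct * n - (n_pred * n_actual).sum()) / mcc_den if mcc_den > 0 else 0.0
    baseline = (n_pred * n_actual).sum() / n**2
    kappa = (acc - baseline) / (1 - baseline) if baseline < 1 else 0.0
    return {"ACC": acc, "BACC": bacc, "MCC": float(mcc), "kappa": float(kappa)}


def brier_score(preds: ScoredPredictions) -> float:
    """Multiclass Brier score loss: mean squared gap between the predicted
    probability vector and the one-hot outcome; range [0, 2], smaller better."""
    onehot = np.zeros_like(preds.probabilities)
    onehot[np.arange(preds.n_samples), preds.true_labels - 1] = 1.0
    return float(((preds.probabilities - onehot) ** 2).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# score-ranking metrics (2-class)


def _check_binary_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D vectors")
    return scores, labels


def enrichment_metrics(scores, labels, x: float = 5.0) -> tuple[float, float]:
    """Enrichment factor and ROC enrichment at a top fraction of x percent.

    EF is the fraction of positives among the top ``ceil(x% * n)`` ranked
    samples divided by the base rate; a tie group straddling the cutoff
    contributes fractionally.  ROC_EF is TPR at FPR = x% (linear ROC
    interpolation) divided by x%.
    """
    scores, labels = _check_binary_scores(scores, labels)
    if not 0 < x < 100:
        raise ValueError("x must be a percentage in (0, 100)")
    n = scores.size
    p = int(labels.sum())
    if p == 0 or p == n:
        raise ValueError("need both positives and negatives")
    pp = math.ceil(x / 100 * n)
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    # fractional count of positives in the top pp, sharing boundary ties
    tp_top = 0.0
    taken = 0
    i = 0
    while i < n and taken < pp:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        group_pos = float(y_sorted[i:j].sum())
        group_size = j - i
        take = min(group_size, pp - taken)
        tp_top += group_pos * take / group_size
        taken += take
        i = j
    ef = (tp_top / pp) / (p / n)
    # ROC enrichment via the tie-grouped ROC polyline
    fpr, tpr = _roc_points(s_sorted, y_sorted, p, n - p)
    tpr_at_x = float(np.interp(x / 100, fpr, tpr))
    roc_ef = tpr_at_x / (x / 100)
    return ef, roc_ef


def _roc_points(s_sorted, y_sorted, p, n_neg):
    """ROC polyline vertices at unique-score boundaries, starting at (0, 0)."""
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    cum_tp = np.cumsum(y_sorted)
    idx = np.append(boundaries, len(s_sorted))
    tp = cum_tp[idx - 1]
    fp = idx - tp
    tpr = np.concatenate(([0.0], tp / p))
    fpr = np.concatenate(([0.0], fp / n_neg))
    return fpr, tpr


def rie_bedroc(scores, labels, alpha: float = 20.0) -> tuple[float, float]:
    """Robust initial enhancement and BEDROC.

    RIE sums exp(-alpha * r_i / n) over the ranks of the positives,
    normalized by the expected sum when positives fall uniformly through
    the list.  Tied scores contribute their expectation over tie-breaking:
    a tie group's positives share the group's rank positions equally
    (the average-rank convention applied outside the exponential would
    bias RIE, since exp is nonlinear).  BEDROC rescales RIE between its
    worst- and best-possible values (positives last / first) to [0, 1].
    """
    scores, labels = _check_binary_scores(scores, labels)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n = scores.size
    p = int(labels.sum())
    if p == 0 or p == n:
        raise ValueError("need both positives and negatives")
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    exp_terms = np.exp(-alpha * np.arange(1, n + 1) / n)
    boundaries = np.concatenate(([0], np.flatnonzero(np.diff(s_sorted)) + 1, [n]))
    numer = 0.0
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        group_pos = float(y_sorted[lo:hi].sum())
        if group_pos:
            numer += group_pos / (hi - lo) * exp_terms[lo:hi].sum()
    # expected sum for P positives uniform over n list positions
    denom = (p / n) * (1 - math.exp(-alpha)) / (math.exp(alpha / n) - 1)
    rie = numer / denom
    best = np.exp(-alpha * np.arange(1, p + 1) / n).sum() / denom
    worst = np.exp(-alpha * np.arange(n - p + 1, n + 1) / n).sum() / denom
    bedroc = (rie - worst) / (best - worst)
    return float(rie), float(bedroc)


def curve_metrics(scores, labels) -> dict[str, float]:
    """Global metrics: AUC, AUAC, AP and the average relative rank of actives.

    AUC is computed by positive-negative pair counting with ties worth 0.5
    (via the rank-sum identity); AUAC and AP are trapezoidal areas over the
    tie-grouped accumulation and precision-recall polylines; r averages the
    fractional best-first ranks of the positives, normalized by n.
    """
    scores, labels = _check_binary_scores(scores, labels)
    n = scores.size
    p = int(labels.sum())
    n_neg = n - p
    if p == 0 or n_neg == 0:
        raise ValueError("need both positives and negatives")
    asc_ranks = rankdata(scores, method="average")
    auc = (asc_ranks[labels].sum() - p * (p + 1) / 2) / (p * n_neg)
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    idx = np.append(boundaries, n)
    cum_tp = np.cumsum(y_sorted)[idx - 1]
    frac = idx / n
    tpr = cum_tp / p
    auac = float(np.trapezoid(np.concatenate(([0.0], tpr)), np.concatenate(([0.0], frac))))
    ppv = cum_tp / idx
    tpr_pts = np.concatenate(([0.0], tpr))
    ppv_pts = np.concatenate(([ppv[0]], ppv))
    ap = float(np.trapezoid(ppv_pts, tpr_pts))
    desc_ranks = rankdata(-scores, method="average")
    r = desc_ranks[labels].sum() / (p * n)
    return {"AUC": float(auc), "AUAC": auac, "AP": ap, "r": float(r)}


# ---------------------------------------------------------------------------
# multiclass aggregation and the full panel


def one_vs_rest_weighted(metric_fn, preds: ScoredPredictions) -> float:
    """Count-weighted one-vs-rest average of a binary metric.

    ``metric_fn(scores, positive_mask, tp, fn, fp, tn) -> float`` is
    evaluated once per class (class j as positive, scores = probability of
    class j) and averaged with actual class counts as weights.  Classes
    with no members get weight 0; NaN class values are skipped and the
    remaining weights renormalized.
    """
    k = preds.n_classes
    predicted = labels_from_probabilities(preds)
    cm = confusion_matrix(preds.true_labels, predicted, k)
    values, weights = [], []
    for j in range(1, k + 1):
        weight = int((preds.true_labels == j).sum())
        if weight == 0:
            continue
        tp, fn, fp, tn = cm.binary(j)
        value = metric_fn(preds.probabilities[:, j - 1], preds.true_labels == j,
                          tp, fn, fp, tn)
        if not math.isnan(value):
            values.append(value)
            weights.append(weight)
    if not weights:
        return math.nan
    return float(np.average(values, weights=weights))


def _binary_panel(preds: ScoredPredictions, x_percent: float, alpha: float,
                  continuity_correction: bool) -> dict[str, float]:
    pos = preds.positive_class
    predicted = labels_from_probabilities(preds)
    cm = confusion_matrix(preds.true_labels, predicted, preds.n_classes)
    tp, fn, fp, tn = cm.binary(pos)
    values = one_sided_rates(tp, fn, fp, tn)
    values.update(composite_local_metrics(tp, fn, fp, tn, continuity_correction))
    scores = preds.probabilities[:, pos - 1]
    mask = preds.true_labels == pos
    ef, roc_ef = enrichment_metrics(scores, mask, x_percent)
    rie, bedroc = rie_bedroc(scores, mask, alpha)
    values.update({"EF": ef, "ROC_EF": roc_ef, "RIE": rie, "BEDROC": bedroc})
    values.update(curve_metrics(scores, mask))
    values["B"] = brier_score(preds)
    return values


def evaluate_panel(
    preds: ScoredPredictions,
    x_percent: float = 5.0,
    alpha: float = 20.0,
    continuity_correction: bool = False,
) -> pd.Series:
    """Evaluate all 28 panel metrics on one prediction set.

    Returns a Series indexed by the panel abbreviations, in panel order.
    """
    k = preds.n_classes
    if k == 2:
        values = _binary_panel(preds, x_percent, alpha, continuity_correction)
    else:
        predicted = labels_from_probabilities(preds)
        cm = confusion_matrix(preds.true_labels, predicted, k)
        values = dict(_multiclass_composites(cm))
        values["B"] = brier_score(preds)

        def _rate(name):
            return lambda s, m, tp, fn, fp, tn: one_sided_rates(tp, fn, fp, tn)[name]

        def _comp(name):
            return lambda s, m, tp, fn, fp, tn: composite_local_metrics(
                tp, fn, fp, tn, continuity_correction)[name]

        for name in _ONE_SIDED:
            values[name] = one_vs_rest_weighted(_rate(name), preds)
        for name in ("F1", "BM", "MK", "LR+", "LR-", "DOR", "J"):
            values[name] = one_vs_rest_weighted(_comp(name), preds)
        values["EF"] = one_vs_rest_weighted(
            lambda s, m, *_: enrichment_metrics(s, m, x_percent)[0], preds)
        values["ROC_EF"] = one_vs_rest_weighted(
            lambda s, m, *_: enrichment_metrics(s, m, x_percent)[1], preds)
        values["RIE"] = one_vs_rest_weighted(
            lambda s, m, *_: rie_bedroc(s, m, alpha)[0], preds)
        values["BEDROC"] = one_vs_rest_weighted(
            lambda s, m, *_: rie_bedroc(s, m, alpha)[1], preds)
        for name in ("AUC", "AUAC", "AP", "r"):
            values[name] = one_vs_rest_weighted(
                lambda s, m, *_, _n=name: curve_metrics(s, m)[_n], preds)
    return pd.Series([values[a] for a in PANEL_ABBREVIATIONS],
                     index=PANEL_ABBREVIATIONS, name=preds.split or None)
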