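"""Sum of ranking differences (SRD).

SRD compares columns of an objects-by-methods matrix against a reference
column: every column (including the reference) is rank-transformed, and a
column's SRD value is the sum over objects of absolute rank differences
from the reference.  Smaller is better — SRD = 0 means the column induces
exactly the reference ranking.

The statistic is validated two ways:

* a randomization test (CRRN, "comparison of ranks with random numbers")
  giving the null distribution of SRD for a random permutation — methods
  whose SRD falls inside the bulk of this null are indistinguishable from
  random ranking;
* leave-one-fold-out cross-validation, recomputing normalized SRD on row
  subsets to attach an uncertainty distribution to every column.

Ties receive fractional (average) ranks throughout, which makes the
statistic symmetric in its two arguments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "rank_with_ties",
    "fuse_reference",
    "srd_values",
    "srd_max",
    "normalize_srd",
    "crrn_null",
    "srd_crossval",
    "CrrnNull",
    "SRDResult",
    "srd_analysis",
]


def rank_with_ties(column: np.ndarray) -> np.ndarray:
    """Fractional (average) ranks of a column, increasing order.

    ``+inf`` ranks above every finite value and ``-inf`` below; NaN is
    rejected because a missing value has no defensible rank.
    """
    column = np.asarray(column, dtype=float)
    if column.ndim != 1:
        raise ValueError("expected a 1-D column")
    if np.isnan(column).any():
        raise ValueError("NaN entries cannot be ranked")
    return rankdata(column, method="average")


def fuse_reference(
    values: np.ndarray,
    rule: str = "mean",
    row_orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Build a data-fusion reference column from an m-by-p matrix.

    ``rule`` is one of ``min``, ``max``, ``mean``, ``median`` or
    ``oriented-best``.  ``oriented-best`` builds the hypothetical best
    method: the row-wise maximum where the row's quantity is
    greater-is-better and the row-wise minimum where it is
    smaller-is-better (``row_orientation``: boolean, True where
    greater-is-better).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected an m-by-p matrix")
    if rule == "min":
        return values.min(axis=1)
    if rule == "max":
        return values.max(axis=1)
    if rule == "mean":
        return values.mean(axis=1)
    if rule == "median":
        return np.median(values, axis=1)
    if rule == "oriented-best":
        if row_orientation is None:
            raise ValueError("oriented-best requires row orientation metadata")
        row_orientation = np.asarray(row_orientation, dtype=bool)
        if row_orientation.shape[0] != values.shape[0]:
            raise ValueError("row_orientation length must match row count")
        return np.where(row_orientation, values.max(axis=1), values.min(axis=1))
    raise ValueError(f"unknown fusion rule: {rule!r}")


def srd_values(matrix: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Raw SRD per column: sum of absolute rank differences vs reference."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need an m-by-p matrix with m >= 2")
    ref_ranks = rank_with_ties(np.asarray(reference, dtype=float))
    if ref_ranks.shape[0] != matrix.shape[0]:
        raise ValueError("reference length must match row count")
    out = np.empty(matrix.shape[1])
    for j in range(matrix.shape[1]):
        out[j] = np.abs(rank_with_ties(matrix[:, j]) - ref_ranks).sum()
    return out


def srd_max(m: int) -> float:
    """Largest attainable SRD for m objects: m^2/2 (even m), (m^2-1)/2 (odd)."""
    if m < 2:
        raise ValueError("need at least two objects")
    return m * m / 2 if m % 2 == 0 else (m * m - 1) / 2


def normalize_srd(raw, m: int):
    """Normalized SRD in percent: 100 * raw / srd_max(m)."""
    raw = np.asarray(raw, dtype=float)
    mx = srd_max(m)
    if np.any(raw > mx + 1e-9):
        raise ValueError(f"raw SRD exceeds the maximum {mx} for m={m}")
    out = 100.0 * raw / mx
    return float(out) if out.ndim == 0 else out


@dataclass
class CrrnNull:
    """Null distribution of normalized SRD under random ranking.

    ``support``/``probs`` give the distribution over normalized SRD values;
    ``cumulative`` is the CDF over the same support (the curve drawn on the
    right axis of an SRD plot); ``q05``/``q95`` are the 5%/95% quantiles.
    """

    m: int
    mode: str
    support: np.ndarray
    probs: np.ndarray
    q05: float
    q95: float

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.probs)

    def quantile(self, q: float) -> float:
        idx = np.searchsorted(self.cumulative, q, side="left")
        idx = min(idx, len(self.support) - 1)
        return float(self.support[idx])


EXACT_ENUMERATION_LIMIT = 9  # 9! = 362,880 permutations enumerate in seconds


def crrn_null(
    m: int,
    mode: str = "auto",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> CrrnNull:
    """Randomization-test null: SRD of a random permutation vs a fixed reference.

    ``mode='exact'`` enumerates all m! permutations (m <= 9);
    ``mode='montecarlo'`` samples ``n_draws`` random permutations;
    ``mode='auto'`` picks exact for small m.
    """
    if m < 2:
        raise ValueError("need at least two objects")
    if mode == "auto":
        mode = "exact" if m <= EXACT_ENUMERATION_LIMIT else "montecarlo"
    ref = np.arange(1, m + 1)
    if mode == "exact":
        if m > EXACT_ENUMERATION_LIMIT:
            raise ValueError(f"exact enumeration limited to m <= {EXACT_ENUMERATION_LIMIT}")
        counts: dict[float, int] = {}
        for perm in itertools.permutations(range(1, m + 1)):
            srd = float(np.abs(np.asarray(perm) - ref).sum())
            counts[srd] = counts.get(srd, 0) + 1
        support_raw = np.array(sorted(counts))
        probs = np.array([counts[s] for s in support_raw], dtype=float)
        probs /= math.factorial(m)
    elif mode == "montecarlo":
        if n_draws < 1000:
            raise ValueError("montecarlo mode requires n_draws >= 1000")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(m) + 1 for _ in range(n_draws)])
        srds = np.abs(perms - ref).sum(axis=1)
        support_raw, freq = np.unique(srds, return_counts=True)
        support_raw = support_raw.astype(float)
        probs = freq / n_draws
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    support = normalize_srd(support_raw, m)
    cdf = np.cumsum(probs)
    q05 = float(support[min(np.searchsorted(cdf, 0.05, side="left"), len(support) - 1)])
    q95 = float(support[min(np.searchsorted(cdf, 0.95, side="left"), len(support) - 1)])
    return CrrnNull(m=m, mode=mode, support=support, probs=probs, q05=q05, q95=q95)


def srd_crossval(
    matrix: np.ndarray,
    reference: np.ndarray,
    folds: int = 5,
    iterations: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Leave-one-fold-out SRD distributions.

    Rows are repartitioned at random into ``folds`` folds in each iteration;
    for every fold, normalized SRD is recomputed on the remaining rows.
    Returns a (folds * iterations)-by-p array of normalized SRD samples.
    """
    matrix = np.asarray(matrix, dtype=float)
    reference = np.asarray(reference, dtype=float)
    m = matrix.shape[0]
    if folds < 2:
        raise ValueError("need at least two folds")
    if m < 2 * folds:
        raise ValueError("need at least 2 rows per fold (m >= 2*folds)")
    rng = np.random.default_rng(seed)
    samples = np.empty((folds * iterations, matrix.shape[1]))
    row = 0
    for _ in range(iterations):
        perm = rng.permutation(m)
        fold_ids = np.array_split(perm, folds)
        for held_out in fold_ids:
            keep = np.setdiff1d(np.arange(m), held_out)
            raw = srd_values(matrix[keep], reference[keep])
            samples[row] = normalize_srd(raw, keep.size)
            row += 1
    return samples


@dataclass
class SRDResult:
    """Full SRD analysis of one evaluation matrix.

    Holds per-column raw and normalized SRD, the CRRN null and, when
    requested, leave-one-fold-out normalized-SRD samples per column.
    """

    columns: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    null: CrrnNull
    cv_samples: np.ndarray | None = None
    reference_rule: str = "mean"
    m: int = field(default=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"column": self.columns, "srd_raw": self.raw, "srd_norm": self.normalized}
        )
        df["crrn_q05"] = self.null.q05
        df["crrn_q95"] = self.null.q95
        if self.cv_samples is not None:
            qs = np.percentile(self.cv_samples, [5, 25, 50, 75, 95], axis=0)
            for name, q in zip(["cv_q05", "cv_q25", "cv_median", "cv_q75", "cv_q95"], qs):
                df[name] = q
        return df.sort_values("srd_norm").reset_index(drop=True)


def srd_analysis(
    frame: pd.DataFrame,
    reference_rule: str = "mean",
    row_orientation: np.ndarray | None = None,
    cv_folds: int | None = 5,
    cv_iterations: int = 10,
    crrn_draws: int = 100_000,
    seed: int | None = None,
) -> SRDResult:
    """One-call SRD run on a DataFrame (objects in rows, methods in columns)."""
    values = frame.to_numpy(dtype=float)
    reference = fuse_reference(values, reference_rule, row_orientation)
    raw = srd_values(values, reference)
    m = values.shape[0]
    null = crrn_null(m, mode="auto", n_draws=crrn_draws, seed=seed)
    cv = None
    if cv_folds is not None and m >= 2 * cv_folds:
        cv = srd_crossval(values, reference, cv_folds, cv_iterations, seed=seed)
    return SRDResult(
        columns=list(frame.columns),
        raw=raw,
        normalized=normalize_srd(raw, m),
        null=null,
        cv_samples=cv,
        reference_rule=reference_rule,
        m=m,
    )
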