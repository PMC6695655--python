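"""Factorial ANOVA of normalized SRD values.

The cross-validated normalized SRD samples are decomposed over the study's
design factors — dataset composition (balanced/imbalanced, F1),
classification type (2-class/multiclass, F2) and either the performance
metric (28 levels) or the classifier (11 levels) as F3 — with the full
three-way fixed-effects model

    SRD = b0 + b1 F1 + b2 F2 + b3 F3 + b12 F1F2 + b13 F1F3 + b23 F2F3
          + b123 F1F2F3.

Type II sums of squares are used; the design is near-balanced, and Type I
and II coincide when it is fully balanced.  Marginal means come with
pooled-variance 95% confidence intervals.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["factorial_anova", "marginal_means"]

FACTORS = ("F1", "F2", "F3")


def _present_factors(table: pd.DataFrame):
    factors = [f for f in FACTORS if f in table.columns and table[f].nunique() > 1]
    if not factors:
        raise ValueError("no factor column with at least two levels")
    return factors


def factorial_anova(
    table: pd.DataFrame, response: str = "srd", alpha: float = 0.05
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA (Type II SS) of a long table.

    ``table`` needs a numeric ``response`` column and factor columns among
    F1/F2/F3.  The full-interaction model requires every factor-level cell
    to hold at least two replicates.  Returns one row per model term with
    sum_sq, df, F, p_value and a significance flag at ``alpha``.
    """
    factors = _present_factors(table)
    cells = table.groupby([table[f] for f in factors], observed=True).size()
    n_cells = int(np.prod([table[f].nunique() for f in factors]))
    if len(cells) < n_cells:
        raise ValueError(
            "empty factor cells: the full-interaction model needs every "
            f"{'x'.join(factors)} combination populated"
        )
    if len(factors) > 1 and (cells < 2).any():
        raise ValueError(
            "cells with a single replicate: the full-interaction model "
            "needs >= 2 replicates per cell"
        )
    formula = f"{response} ~ " + " * ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(columns={"PR(>F)": "p_value"})
    aov.index = [
        idx.replace("C(", "").replace(")", "").replace(":", "x") for idx in aov.index
    ]
    aov["significant"] = aov["p_value"] < alpha
    return aov


def marginal_means(
    table: pd.DataFrame,
    factors: list[str] | tuple[str, ...],
    response: str = "srd",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Marginal means with pooled-variance confidence intervals.

    The residual variance is pooled over the finest cells of all factors
    present in the table; the CI half-width for a group of n values is
    t(1 - alpha/2, df_resid) * sqrt(MSE / n).
    """
    all_factors = [f for f in FACTORS if f in table.columns]
    if not all_factors:
        raise ValueError("no factor column (F1/F2/F3) in the table")
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"factor {f!r} absent from the table")
    groups = table.groupby([table[f] for f in all_factors], observed=True)[response]
    ss_resid = float(((table[response] - groups.transform("mean")) ** 2).sum())
    df_resid = len(table) - groups.ngroups
    out = (
        table.groupby(list(factors), observed=True)[response]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    if df_resid > 0 and ss_resid > 0:
        mse = ss_resid / df_resid
        half = stats.t.ppf(1 - alpha / 2, df_resid) * np.sqrt(mse / out["n"])
    else:  # no within-cell replication: degenerate zero-width intervals
        half = np.zeros(len(out))
    out["ci_low"] = out["mean"] - half
    out["ci_high"] = out["mean"] + half
    return out


def build_long_table(cv_samples: dict, level_name: str = "F3") -> pd.DataFrame:
    """Stack cross-validated SRD samples into an ANOVA long table.

    ``cv_samples`` maps (F1 level, F2 level) -> DataFrame whose columns are
    the F3 levels and whose rows are cross-validation replicates.
    """
    records = []
    for (f1, f2), frame in cv_samples.items():
        for level in frame.columns:
            for rep, value in enumerate(frame[level].to_numpy()):
                records.append(
                    {"srd": float(value), "F1": f1, "F2": f2,
                     level_name: level, "replicate": rep}
                )
    return pd.DataFrame.from_records(records)


def type1_error_rate(  # used by the null-calibration checks
    n_repetitions: int,
    levels: int = 4,
    replicates: int = 3,
    term: str = "F3",
    seed: int | None = None,
) -> float:
    """Empirical rejection rate of one ANOVA term under a pure-noise model.

    Simulates ``n_repetitions`` balanced 2 x 2 x ``levels`` tables of
    i.i.d. Gaussian noise and reports the fraction where ``term`` is
    declared significant at the 5% level (should sit near 0.05).
    """
    rng = np.random.default_rng(seed)
    grid = list(itertools.product(["bal", "imb"], ["2c", "mc"], range(levels)))
    base = pd.DataFrame(
        [(f1, f2, f"L{f3}") for f1, f2, f3 in grid for _ in range(replicates)],
        columns=["F1", "F2", "F3"],
    )
    hits = 0
    for _ in range(n_repetitions):
        tab = base.copy()
        tab["srd"] = rng.standard_normal(len(tab))
        aov = factorial_anova(tab)
        if bool(aov.loc[term, "significant"]):
            hits += 1
    return hits / n_repetitions
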