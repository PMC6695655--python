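"""Pairwise SRD comparison (COVAT: comparison with one variable at a time).

Every column of an evaluation matrix is taken in turn as the SRD reference
for all others, yielding a symmetric p-by-p matrix of normalized SRD values
(zero diagonal).  Rows and columns are reordered by increasing row-wise
mean, so clusters of similarly behaving methods collect along the diagonal.
The color-scale contract for heatmaps is absolute 0-100, which keeps
different COVAT runs visually comparable.

Cluster boundaries are deliberately not computed: grouping of the ordered
matrix is left to the reader (or, as a clearly separate extension, to any
standard agglomerative procedure applied downstream).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .srd import normalize_srd, srd_values

__all__ = ["covat_matrix", "covat_heatmap"]


def covat_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Ordered symmetric matrix of pairwise normalized SRD values.

    Entry (i, j) is the normalized SRD of column i with column j as the
    reference.  Rows/columns are reordered by increasing row-wise mean.
    """
    values = frame.to_numpy(dtype=float)
    m, p = values.shape
    if p < 2:
        raise ValueError("need at least two columns")
    out = np.zeros((p, p))
    for j in range(p):
        out[:, j] = normalize_srd(srd_values(values, values[:, j]), m)
    order = np.argsort(out.mean(axis=1), kind="stable")
    cols = [frame.columns[i] for i in order]
    return pd.DataFrame(out[np.ix_(order, order)], index=cols, columns=cols)


def covat_heatmap(ordered: pd.DataFrame, ax=None, cmap: str = "viridis"):
    """Heatmap of an ordered COVAT matrix on the absolute 0-100 scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.3 * len(ordered) + 2,) * 2)
    im = ax.imshow(ordered.to_numpy(), vmin=0, vmax=100, cmap=cmap)
    ax.set_xticks(range(len(ordered)), ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ordered)), ordered.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="normalized SRD [%]")
    return ax
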