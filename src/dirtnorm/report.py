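"""Report matrices: heatmap input, set overlaps, pair correlations."""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import normalized_matrix, rle_size_factors
from .io import CountMatrix

logger = logging.getLogger(__name__)


def heatmap_matrix(
    values: pd.DataFrame,
    order_by: pd.Series,
    top_k: int = 50,
    ascending: bool = True,
) -> pd.DataFrame:
    """Top rows normalized to their own mean, ready for heatmap rendering.

    Rows of ``values`` are ranked by ``order_by`` (typically the
    adjusted p of the row's record; lowest first), the top ``top_k``
    selected, and each selected row divided by its mean over the shown
    samples — so every row of the output has mean 1, values above 1
    read "above the row's average".  ``top_k`` larger than the table is
    clamped with a warning.
    """
    order_by = order_by.loc[values.index]
    if top_k > len(values):
        logger.warning("top_k=%d exceeds %d rows; clamping", top_k, len(values))
        top_k = len(values)
    chosen = order_by.sort_values(ascending=ascending, kind="stable").index[:top_k]
    sub = values.loc[chosen].astype(float)
    return sub.div(sub.mean(axis=1), axis=0)


def overlap_counts(
    list_a: Sequence[str], list_b: Sequence[str], list_c: Sequence[str]
) -> dict[str, int]:
    """Three-set Venn region counts (inputs treated as sets)."""
    a, b, c = set(list_a), set(list_b), set(list_c)
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(a & b & c),
    }


def pair_correlation(
    cm: CountMatrix,
    gene_a: str,
    gene_b: str,
    samples: Sequence[str],
) -> float:
    """Pearson correlation of two genes' mean-scaled RLE expression.

    Expression is RLE-normalized over ``samples`` and each gene scaled
    by its average across those samples (the construction behind
    DEG–index correlation panels over control samples).  Returns NaN
    when either gene has zero variance.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    sub = cm.subset_samples(list(samples))
    norm = normalized_matrix(sub, rle_size_factors(sub))
    x = norm.loc[gene_a].to_numpy(dtype=float)
    y = norm.loc[gene_b].to_numpy(dtype=float)
    x = x / x.mean() if x.mean() != 0 else x
    y = y / y.mean() if y.mean() != 0 else y
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.corrcoef(x, y)[0, 1])


def plot_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Render a heatmap matrix to an image file (red above 1, blue below)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, matrix.shape[1] * 0.5),
                                    max(4, matrix.shape[0] * 0.15)))
    vmax = float(np.nanmax(np.abs(np.log2(matrix.to_numpy(dtype=float)))))
    im = ax.imshow(np.log2(matrix.to_numpy(dtype=float)), aspect="auto",
                   cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="log2(value / row mean)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
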