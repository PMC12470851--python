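"""Shared statistical primitives.

Two pieces are used throughout the pipeline: the equal-variance
two-sample two-tailed t-test applied to ratio values, CPM values and
normalized expression alike, and Benjamini–Hochberg step-up adjustment
with an explicit rank multiplier ``m`` (the analysis uses data-dependent
ranks: the number of records surviving per-target deduplication for the
ratio tests, the full gene count for the global-normalization arm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """Equal-variance two-sample t-test outcome."""

    t_statistic: float
    df: int
    p_value: float


def t_test_equal_var(group_a, group_b) -> TestResult:
    """Two-tailed pooled-variance t-test of two samples.

    With zero pooled variance the t statistic is degenerate; the limit
    behaviour is used: p = 1 when the means are equal (t = 0), p = 0
    otherwise (|t| -> inf).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("groups must be 1-D")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, df, p = _t_test_rows(a[None, :], b[None, :])
    return TestResult(float(t[0]), int(df), float(p[0]))


def _t_test_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Vectorized pooled t-test over the rows of ``a`` (n × n_a) vs ``b`` (n × n_b).

    Returns (t, df, p) with the same degenerate-variance limits as
    :func:`t_test_equal_var`.
    """
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
    sp2 = (ssa + ssb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = np.empty_like(t)
    ok = se > 0
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df)
    # zero pooled variance: limit behaviour
    same = ~ok & (diff == 0)
    p[same] = 1.0
    t[same] = 0.0
    apart = ~ok & (diff != 0)
    p[apart] = 0.0
    t[apart] = np.sign(diff[apart]) * np.inf
    return t, df, p


def bh_adjust(p_values, m: int) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with explicit rank ``m``.

    ``adj_i = min_{j >= i} m * p_(j) / j`` over the ascending-sorted
    vector, original order restored, values capped at 1.  ``m`` may
    exceed ``len(p_values)`` (e.g. adjusting a filtered subset against
    the size of the original family).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of p-values ({p.size})")
    if p.size == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    scaled = p[order] * m / ranks
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty_like(p)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj
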