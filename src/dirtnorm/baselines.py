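"""Global-normalization baselines: RLE and TMM scaling factors.

These are the two standard library-composition corrections for bulk
RNA-Seq count matrices, implemented natively so the comparator analyses
(t-tests on globally normalized values, expression bar/correlation
panels) run without external fitting machinery.

RLE (relative log expression, the median-of-ratios size factor): each
gene's geometric mean across samples forms a pseudo-reference; a
sample's factor is the median over reference genes of its count divided
by that pseudo-reference.  Genes with a zero count in any sample are
excluded from the reference set.

TMM (trimmed mean of M-values): one sample is chosen as reference (the
one whose upper-quartile CPM is closest to the mean upper quartile);
for every other sample the per-gene log2 fold changes M against the
reference are doubly trimmed — by M (fraction ``trim_m`` from each
tail) and by average log intensity A (fraction ``trim_a`` from each
tail) — and the factor is 2 to the precision-weighted mean of the
surviving M values, with delta-method binomial weights.  Factors are
rescaled to geometric mean 1.  Trim fractions follow the canonical
convention (0.30 of M and 0.05 of A trimmed from each tail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleDesign, library_sizes
from .stats import _t_test_rows, bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScalingFactors:
    method: str  # "rle" | "tmm"
    factors: pd.Series  # per sample, > 0

    def __post_init__(self) -> None:
        if self.method not in ("rle", "tmm"):
            raise ValueError(f"unknown method {self.method!r}")
        f = self.factors.to_numpy(dtype=float)
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("scaling factors must be finite and positive")


def rle_size_factors(cm: CountMatrix) -> ScalingFactors:
    """Median-of-ratios size factors."""
    counts = cm.counts.to_numpy(dtype=float)
    ref_mask = (counts > 0).all(axis=1)
    if not ref_mask.any():
        raise ValueError("no gene has positive counts in every sample; "
                         "RLE reference set is empty")
    ref = counts[ref_mask]
    gm = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / gm[:, None], axis=0)
    return ScalingFactors("rle", pd.Series(factors, index=cm.counts.columns))


def _upper_quartile_cpm(counts: np.ndarray, libsizes: np.ndarray) -> np.ndarray:
    uq = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        col = counts[:, j]
        pos = col[col > 0]
        uq[j] = np.quantile(pos / libsizes[j] * 1e6, 0.75)
    return uq


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> ScalingFactors:
    """Trimmed-mean-of-M-values scaling factors.

    ``trim_m`` / ``trim_a`` are the fractions trimmed from *each* tail
    of the M and A distributions (the standard 30%/5% doubly trimmed
    scheme).  ``ref_sample`` overrides the automatic
    closest-to-mean-upper-quartile reference choice.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = cm.counts.to_numpy(dtype=float)
    libs = library_sizes(cm).to_numpy(dtype=float)
    samples = list(cm.counts.columns)
    if ref_sample is None:
        uq = _upper_quartile_cpm(counts, libs)
        r = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        r = samples.index(ref_sample)

    factors = np.ones(len(samples))
    yr = counts[:, r]
    nr = libs[r]
    for j in range(len(samples)):
        if j == r:
            continue
        ys = counts[:, j]
        ns = libs[j]
        both = (ys > 0) & (yr > 0)
        s = ys[both] / ns
        rr = yr[both] / nr
        m = np.log2(s / rr)
        a = 0.5 * np.log2(s * rr)
        w = (ns - ys[both]) / (ns * ys[both]) + (nr - yr[both]) / (nr * yr[both])
        n = m.size
        if n == 0:
            logger.warning("TMM: no shared positive genes for sample %s", samples[j])
            continue
        if np.max(np.abs(m)) < 1e-6:
            continue  # already perfectly matched (pure depth scaling)
        # rank-based double trim, each tail, following the standard scheme
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            logger.warning("TMM: trimming left no genes for sample %s; factor 1",
                           samples[j])
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return ScalingFactors("tmm", pd.Series(factors, index=samples))


def normalized_matrix(cm: CountMatrix, factors: ScalingFactors) -> pd.DataFrame:
    """Counts on the normalized scale implied by ``factors``.

    RLE: count / size factor (the DESeq-style normalized count).  TMM:
    count / (library size × factor) × mean effective library size —
    TMM-scaled counts on a common-depth scale.  The scale is recorded
    in ``DataFrame.attrs['scale']``.
    """
    if list(factors.factors.index) != list(cm.counts.columns):
        if set(factors.factors.index) != set(cm.counts.columns):
            raise ValueError("factor samples do not match matrix samples")
        factors = ScalingFactors(factors.method,
                                 factors.factors[cm.counts.columns])
    if factors.method == "rle":
        out = cm.counts.div(factors.factors, axis=1)
        out.attrs["scale"] = "counts / RLE size factor"
    else:
        libs = library_sizes(cm).astype(float)
        eff = libs * factors.factors
        out = cm.counts.div(eff, axis=1) * eff.mean()
        out.attrs["scale"] = ("counts / (library size x TMM factor), "
                              "rescaled to the mean effective depth")
    return out


def baseline_de_tests(
    cm: CountMatrix,
    design: SampleDesign,
    method: str,
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Per-gene t-tests on globally normalized values.

    Factors are computed on the tested cohort's samples; each gene gets
    an equal-variance t-test (control vs treated) on the normalized
    values plus BH adjustment with m equal to the gene count.  Returns
    a DataFrame indexed by gene with t, p, p_adj.
    """
    if method not in ("rle", "tmm"):
        raise ValueError(f"method must be 'rle' or 'tmm', got {method!r}")
    samples = design.samples(cohort=cohort)
    controls = design.samples(cohort=cohort, condition="control")
    treated = design.samples(cohort=cohort, condition="treated")
    if len(controls) < 2 or len(treated) < 2:
        raise ValueError("need >= 2 samples per condition")
    sub = cm.subset_samples(samples)
    factors = rle_size_factors(sub) if method == "rle" else tmm_factors(sub)
    norm = normalized_matrix(sub, factors)
    a = norm[controls].to_numpy(dtype=float)
    b = norm[treated].to_numpy(dtype=float)
    t, _, p = _t_test_rows(a, b)
    p_adj = bh_adjust(p, m=len(p))
    return pd.DataFrame({"t": t, "p": p, "p_adj": p_adj}, index=norm.index)
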