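"""The DiRT method proper.

A DiRT ("DEG-by-index ratio transformation") replaces a target gene's
expression measure by the per-sample ratio of its raw read count to the
read count of a partner ("index") gene chosen specifically for that
target.  A good index gene tracks the target tightly across untreated
samples — the ratio is nearly constant under baseline conditions — but
does not itself respond to treatment, so a treatment effect on the
target shows up as a shift of the ratio between conditions.

Candidate indexes are ranked by the normalized standard deviation (NSD)
of the target/partner count ratio across the discovery control samples:
the sample standard deviation (n−1 denominator) of the per-sample ratio
divided by its mean, i.e. the coefficient of variation.  Per target the
``k_candidates`` lowest-NSD partners form the candidate database; each
candidate ratio is tested between discovery conditions with an
equal-variance t-test, candidates whose denominator gene is itself
differentially expressed on the CPM scale are discarded, one record per
target (lowest raw p) survives deduplication, and Benjamini–Hochberg
adjustment runs with m equal to the number of surviving records.

Because every statistic is a within-sample count ratio, multiplying all
counts of a sample by any constant changes nothing: the method is
exactly invariant to library depth and to global scaling, which is its
core advantage over global normalization under batch effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleDesign, cpm
from .stats import _t_test_rows, bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirtParams:
    """Tunable parameters of the DiRT pipeline.

    top_n_genes
        Abundance filter size; the analysis keeps this many of the most
        abundant genes before any pairing.
    k_candidates
        Number of lowest-NSD index candidates retained per target.
    denom_de_alpha
        Unadjusted CPM t-test threshold above which a denominator gene
        counts as treatment-neutral (records with denominator p below
        this are discarded as potential DEG–DEG artifacts).
    discovery_alpha / validation_alpha / strict_validation_alpha
        Adjusted-p thresholds for calling a DiRT in discovery, for the
        validation criterion, and for the stricter validation call.
    chunk_size
        Number of target genes scored per block in the pairwise NSD
        scan; a pure memory/performance knob with no effect on results.
    pseudocount
        Added to every count before forming ratios when > 0.  Default 0:
        the abundance filter makes zeros rare and pseudocounts distort
        ratios, so zero-count partners are excluded instead.
    """

    top_n_genes: int = 10_000
    k_candidates: int = 10
    denom_de_alpha: float = 0.1
    discovery_alpha: float = 0.05
    validation_alpha: float = 0.05
    strict_validation_alpha: float = 0.01
    chunk_size: int = 128
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        for name in ("denom_de_alpha", "discovery_alpha", "validation_alpha",
                     "strict_validation_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.k_candidates < 1:
            raise ValueError("k_candidates must be >= 1")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass(frozen=True)
class CandidatePair:
    """A (target, index) pairing with its control-sample ratio NSD."""

    target_gene: str
    index_gene: str
    nsd: float

    def __post_init__(self) -> None:
        if self.target_gene == self.index_gene:
            raise ValueError("self-pairing is forbidden")
        if self.nsd < 0:
            raise ValueError("nsd must be >= 0")


@dataclass
class DiRTRecord:
    """A numerator/denominator gene pair carried through the pipeline."""

    numerator: str
    denominator: str
    nsd: float
    ratio_values: pd.Series  # per discovery sample
    p_discovery: float | None = None
    t_discovery: float | None = None
    p_adj_discovery: float | None = None
    ratio_values_validation: pd.Series | None = None
    p_validation: float | None = None
    p_adj_validation: float | None = None
    validated: bool | None = None
    strictly_validated: bool | None = None
    unvalidatable: bool = False
    pair_class: str | None = None  # deg_index / index_deg / deg_deg / unresolved
    opposite_regulation: bool | None = None


def ratio_profile(
    cm: CountMatrix,
    numerator: str,
    denominator: str,
    samples: Sequence[str],
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-sample RC_numerator / RC_denominator over ``samples``.

    Raw counts, no log.  A zero denominator count in any requested
    sample is a hard error at this level (the pairwise scan instead
    skips such partners as ineligible).
    """
    if numerator == denominator:
        raise ValueError("self-pairing is forbidden")
    num = cm.counts.loc[numerator, list(samples)].astype(float) + pseudocount
    den = cm.counts.loc[denominator, list(samples)].astype(float) + pseudocount
    if (den == 0).any():
        bad = den.index[den == 0].tolist()
        raise ZeroDivisionError(
            f"denominator {denominator!r} has zero counts in samples {bad}"
        )
    return num / den


def nsd(ratio) -> float:
    """Normalized standard deviation of a ratio vector.

    Sample standard deviation (n−1 denominator) divided by the
    arithmetic mean — the coefficient of variation.  Scale-free: a
    constant rescaling of the vector leaves it unchanged.
    """
    r = np.asarray(ratio, dtype=float)
    if r.size < 2:
        raise ValueError("nsd needs at least 2 values")
    return float(r.std(ddof=1) / r.mean())


def _lex_ranks(gene_ids: Sequence[str]) -> np.ndarray:
    """Rank of each gene id in lexicographic order (for tie-breaking)."""
    order = np.argsort(np.asarray(gene_ids, dtype=object), kind="stable")
    ranks = np.empty(len(gene_ids), dtype=np.int64)
    ranks[order] = np.arange(len(gene_ids))
    return ranks


def select_index_candidates(
    cm: CountMatrix,
    design: SampleDesign,
    params: DirtParams,
    chunk_size: int | None = None,
) -> list[CandidatePair]:
    """Lowest-NSD index candidates for every target gene.

    NSD is computed over the discovery-cohort control samples only.
    Partners with any zero count in those samples are ineligible (unless
    a pseudocount is configured), as are self-pairs.  Ties in NSD break
    toward the lexicographically smaller partner id.  The scan is
    chunked over targets so peak memory stays at
    ``chunk_size × n_genes × n_controls`` floats; results are identical
    for any chunk size.

    Output ordering is canonical: targets in lexicographic order, each
    target's candidates by ascending (nsd, partner id).
    """
    k = params.k_candidates
    controls = design.samples(cohort="discovery", condition="control")
    if len(controls) < 2:
        raise ValueError("need at least 2 discovery control samples")
    chunk = chunk_size if chunk_size is not None else params.chunk_size

    gene_ids = np.asarray(cm.gene_ids, dtype=object)
    n = len(gene_ids)
    counts = cm.counts[controls].to_numpy(dtype=float)
    if params.pseudocount > 0:
        counts = counts + params.pseudocount
    eligible = (counts > 0).all(axis=1)  # usable as a denominator
    lex = _lex_ranks(gene_ids)
    lex_order = np.argsort(lex)

    pairs: list[CandidatePair] = []
    failures: list[str] = []
    results: dict[str, list[CandidatePair]] = {}
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = counts[start:stop]  # b × S
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = block[:, None, :] / counts[None, :, :]  # b × n × S
            mean = ratios.mean(axis=2)
            sd = ratios.std(axis=2, ddof=1)
            nsd_block = sd / mean
        nsd_block[:, ~eligible] = np.inf
        nsd_block[~np.isfinite(nsd_block)] = np.inf
        for i in range(stop - start):
            gi = start + i
            row = nsd_block[i].copy()
            row[gi] = np.inf  # no self-pairing
            finite = np.isfinite(row)
            if finite.sum() < k:
                failures.append(str(gene_ids[gi]))
                continue
            # exact k-smallest with lexicographic ties: find the k-th
            # smallest value, gather everything <= it, then sort that
            # small set by (nsd, partner id)
            kth = np.partition(row, k - 1)[k - 1]
            cand = np.flatnonzero(row <= kth)
            sel = cand[np.lexsort((lex[cand], row[cand]))][:k]
            results[str(gene_ids[gi])] = [
                CandidatePair(str(gene_ids[gi]), str(gene_ids[j]), float(row[j]))
                for j in sel
            ]
    if failures:
        raise ValueError(
            f"{len(failures)} gene(s) with fewer than k={k} eligible index "
            f"partners (zero counts in discovery controls): {failures[:10]}"
        )
    for gid in sorted(results):
        pairs.extend(results[gid])
    return pairs


def build_candidate_db(
    cm: CountMatrix,
    design: SampleDesign,
    candidates: Iterable[CandidatePair],
    params: DirtParams | None = None,
) -> list[DiRTRecord]:
    """Materialize DiRT records (per-sample ratio values) for candidates.

    Ratio values run over all discovery samples (controls and treated).
    Candidates whose denominator has a zero count in a treated discovery
    sample cannot form a ratio there; those records are dropped with a
    logged warning (control zeros were already excluded upstream).
    """
    pc = params.pseudocount if params is not None else 0.0
    samples = design.samples(cohort="discovery")
    candidates = list(candidates)
    arr = cm.counts[samples].to_numpy(dtype=float) + pc
    row_of = {g: i for i, g in enumerate(cm.gene_ids)}
    num_i = np.fromiter((row_of[c.target_gene] for c in candidates), dtype=np.int64,
                        count=len(candidates))
    den_i = np.fromiter((row_of[c.index_gene] for c in candidates), dtype=np.int64,
                        count=len(candidates))
    den_rows = arr[den_i]
    bad = (den_rows == 0).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = arr[num_i] / den_rows
    index = pd.Index(samples)
    records: list[DiRTRecord] = []
    for j, cand in enumerate(candidates):
        if bad[j]:
            logger.warning(
                "dropping candidate %s/%s: zero denominator count in discovery",
                cand.target_gene, cand.index_gene,
            )
            continue
        records.append(
            DiRTRecord(
                numerator=cand.target_gene,
                denominator=cand.index_gene,
                nsd=cand.nsd,
                ratio_values=pd.Series(ratios[j], index=index),
            )
        )
    if bad.any():
        logger.warning("dropped %d candidate(s) with zero treated denominators",
                       int(bad.sum()))
    return records


def test_dirts(db: Sequence[DiRTRecord], design: SampleDesign) -> list[DiRTRecord]:
    """Equal-variance t-test of each record's ratios, control vs treated.

    Sets ``p_discovery`` (and the t statistic) on every record.
    """
    controls = design.samples(cohort="discovery", condition="control")
    treated = design.samples(cohort="discovery", condition="treated")
    if len(controls) < 2 or len(treated) < 2:
        raise ValueError("need >= 2 control and >= 2 treated discovery samples")
    if not db:
        return []
    mat = np.vstack([rec.ratio_values.to_numpy(dtype=float) for rec in db])
    sample_order = list(db[0].ratio_values.index)
    ci = [sample_order.index(s) for s in controls]
    ti = [sample_order.index(s) for s in treated]
    t, _, p = _t_test_rows(mat[:, ci], mat[:, ti])
    for rec, ti, pi in zip(db, t, p):
        rec.p_discovery = float(pi)
        rec.t_discovery = float(ti)
    return list(db)


def per_gene_cpm_tests(
    cm: CountMatrix, design: SampleDesign
) -> pd.DataFrame:
    """Per-gene CPM-scale equal-variance t-test, discovery control vs treated.

    Returns a DataFrame indexed by gene id with columns ``t``, ``p`` and
    ``log2fc`` (log2 of mean treated CPM over mean control CPM; signs
    feed the DEG–DEG opposite-regulation annotation).  Unadjusted p —
    this is the denominator screen of the pipeline, not a DE call.
    """
    controls = design.samples(cohort="discovery", condition="control")
    treated = design.samples(cohort="discovery", condition="treated")
    mat = cpm(cm)
    a = mat[controls].to_numpy(dtype=float)
    b = mat[treated].to_numpy(dtype=float)
    t, _, p = _t_test_rows(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(b.mean(axis=1) / a.mean(axis=1))
    return pd.DataFrame({"t": t, "p": p, "log2fc": lfc}, index=cm.counts.index)


def denominator_deg_filter(
    db: Sequence[DiRTRecord],
    cm: CountMatrix,
    design: SampleDesign,
    params: DirtParams,
    per_gene_p: Mapping[str, float] | pd.Series | None = None,
) -> list[DiRTRecord]:
    """Discard records whose denominator gene looks differentially expressed.

    By default each gene gets one CPM-scale t-test (discovery control vs
    treated, unadjusted); records whose denominator p falls below
    ``denom_de_alpha`` are removed, suppressing DEG–DEG artifact pairs.
    An externally supplied per-gene p table (e.g. Wald p-values from a
    count-model fit) can replace the CPM screen.
    """
    if per_gene_p is None:
        per_gene_p = per_gene_cpm_tests(cm, design)["p"]
    out = []
    for rec in db:
        try:
            p = float(per_gene_p[rec.denominator])
        except KeyError as exc:
            raise KeyError(f"no DE p-value for denominator {rec.denominator!r}") from exc
        if p >= params.denom_de_alpha:
            out.append(rec)
    return out


def dedup_and_adjust(
    db: Sequence[DiRTRecord], params: DirtParams
) -> list[DiRTRecord]:
    """One record per target gene, then BH adjustment.

    Per numerator the record with the lowest raw discovery p survives
    (ties toward the lexicographically smaller denominator); the
    surviving p-values are BH-adjusted with m equal to their count.
    Output sorted by numerator id.
    """
    best: dict[str, DiRTRecord] = {}
    for rec in db:
        if rec.p_discovery is None:
            raise ValueError("p_discovery unset; run test_dirts first")
        cur = best.get(rec.numerator)
        if (
            cur is None
            or rec.p_discovery < cur.p_discovery
            or (rec.p_discovery == cur.p_discovery and rec.denominator < cur.denominator)
        ):
            best[rec.numerator] = rec
    retained = [best[g] for g in sorted(best)]
    if retained:
        adj = bh_adjust([rec.p_discovery for rec in retained], m=len(retained))
        for rec, a in zip(retained, adj):
            rec.p_adj_discovery = float(a)
    return retained


def call_dirts(db: Sequence[DiRTRecord], params: DirtParams) -> list[DiRTRecord]:
    """Records with adjusted discovery p strictly below ``discovery_alpha``.

    Sorted by ascending adjusted p, then numerator id.
    """
    called = [rec for rec in db if rec.p_adj_discovery is not None
              and rec.p_adj_discovery < params.discovery_alpha]
    called.sort(key=lambda r: (r.p_adj_discovery, r.numerator))
    return called


def separation_threshold(record: DiRTRecord, design: SampleDesign) -> float:
    """Midpoint of the discovery control and treated DiRT-value means.

    Used only for reporting which side each validation sample falls on.
    """
    controls = design.samples(cohort="discovery", condition="control")
    treated = design.samples(cohort="discovery", condition="treated")
    mc = float(record.ratio_values[controls].mean())
    mt = float(record.ratio_values[treated].mean())
    return 0.5 * (mc + mt)


def threshold_consistency(record: DiRTRecord, design: SampleDesign) -> bool:
    """True when every validation sample falls on its condition's side
    of the discovery separation threshold ("complete consistency")."""
    if record.ratio_values_validation is None:
        raise ValueError("validation ratios not computed")
    thr = separation_threshold(record, design)
    controls = design.samples(cohort="discovery", condition="control")
    treated = design.samples(cohort="discovery", condition="treated")
    ctrl_high = record.ratio_values[controls].mean() > record.ratio_values[treated].mean()
    vc = record.ratio_values_validation[
        design.samples(cohort="validation", condition="control")]
    vt = record.ratio_values_validation[
        design.samples(cohort="validation", condition="treated")]
    if ctrl_high:
        return bool((vc > thr).all() and (vt < thr).all())
    return bool((vc < thr).all() and (vt > thr).all())


def records_to_frame(db: Sequence[DiRTRecord]) -> pd.DataFrame:
    """Flatten DiRT records into a table (ratio columns prefixed ``ratio_``)."""
    rows = []
    for rec in db:
        row: dict = {
            "numerator": rec.numerator,
            "denominator": rec.denominator,
            "nsd": rec.nsd,
        }
        for s, v in rec.ratio_values.items():
            row[f"ratio_{s}"] = v
        row["t_discovery"] = rec.t_discovery
        row["p_discovery"] = rec.p_discovery
        row["p_adj_discovery"] = rec.p_adj_discovery
        if rec.ratio_values_validation is not None:
            for s, v in rec.ratio_values_validation.items():
                row[f"ratio_{s}"] = v
        for k in ("p_validation", "p_adj_validation", "validated",
                  "strictly_validated", "unvalidatable", "pair_class",
                  "opposite_regulation"):
            v = getattr(rec, k)
            if v is not None:
                row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)
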