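"""Naive reference implementation of the ratio pipeline.

Deliberately independent of the package internals: plain Python loops
over all gene pairs, statistics from the standard library / scipy, a
direct step-up loop for BH.  Used as the oracle for record-for-record
equivalence tests on small matrices; never called by the package.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as sps


def naive_bh(pvals: list[float], m: int) -> list[float]:
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    adj = [None] * len(pvals)
    running = math.inf
    for rank_pos in range(len(pvals) - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, pvals[i] * m / (rank_pos + 1))
        adj[i] = min(running, 1.0)
    return adj


def naive_t_test(a: list[float], b: list[float]) -> float:
    va = statistics.variance(a)
    vb = statistics.variance(b)
    if va == 0 and vb == 0:
        return 1.0 if statistics.mean(a) == statistics.mean(b) else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


@dataclass
class NaiveRecord:
    numerator: str
    denominator: str
    nsd: float
    ratios: dict[str, float]
    p_discovery: float | None = None
    p_adj_discovery: float | None = None
    ratios_validation: dict[str, float] = field(default_factory=dict)
    p_validation: float | None = None
    p_adj_validation: float | None = None
    validated: bool | None = None
    unvalidatable: bool = False


def naive_pipeline(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    k: int = 10,
    top_n: int | None = None,
    denom_alpha: float = 0.1,
    discovery_alpha: float = 0.05,
    validation_alpha: float = 0.05,
) -> dict:
    """Full pipeline with explicit loops; returns every intermediate."""
    des = design.set_index("sample_id")
    disc = [s for s in counts.columns if des.loc[s, "cohort"] == "discovery"]
    disc_c = [s for s in disc if des.loc[s, "condition"] == "control"]
    disc_t = [s for s in disc if des.loc[s, "condition"] == "treated"]
    val = [s for s in counts.columns if des.loc[s, "cohort"] == "validation"]
    val_c = [s for s in val if des.loc[s, "condition"] == "control"]
    val_t = [s for s in val if des.loc[s, "condition"] == "treated"]

    # abundance filter: total over discovery samples, ties by gene id
    if top_n is not None:
        totals = {g: sum(counts.loc[g, s] for s in disc) for g in counts.index}
        keep = sorted(counts.index, key=lambda g: (-totals[g], g))[:top_n]
        counts = counts.loc[keep]

    genes = list(counts.index)

    # candidate selection: CV of target/partner over discovery controls
    candidates: list[tuple[str, str, float]] = []
    for target in sorted(genes):
        scored = []
        for partner in genes:
            if partner == target:
                continue
            if any(counts.loc[partner, s] == 0 for s in disc_c):
                continue
            ratios = [counts.loc[target, s] / counts.loc[partner, s] for s in disc_c]
            mean = statistics.mean(ratios)
            if mean == 0:
                continue
            scored.append((statistics.stdev(ratios) / mean, partner))
        scored.sort(key=lambda x: (x[0], x[1]))
        assert len(scored) >= k, f"{target}: fewer than {k} eligible partners"
        for nsd_val, partner in scored[:k]:
            candidates.append((target, partner, nsd_val))

    # candidate DB over all discovery samples; drop zero treated denominators
    records: list[NaiveRecord] = []
    for target, partner, nsd_val in candidates:
        if any(counts.loc[partner, s] == 0 for s in disc):
            continue
        ratios = {s: counts.loc[target, s] / counts.loc[partner, s] for s in disc}
        records.append(NaiveRecord(target, partner, nsd_val, ratios))

    # discovery t-tests on the ratios
    for rec in records:
        rec.p_discovery = naive_t_test([rec.ratios[s] for s in disc_c],
                                       [rec.ratios[s] for s in disc_t])

    # per-gene CPM t-tests for the denominator screen
    libsize = {s: counts[s].sum() for s in counts.columns}
    gene_p = {}
    for g in genes:
        a = [counts.loc[g, s] / libsize[s] * 1e6 for s in disc_c]
        b = [counts.loc[g, s] / libsize[s] * 1e6 for s in disc_t]
        gene_p[g] = naive_t_test(a, b)
    records = [r for r in records if gene_p[r.denominator] >= denom_alpha]

    # dedup per target: lowest raw p, ties toward smaller denominator id
    best: dict[str, NaiveRecord] = {}
    for rec in records:
        cur = best.get(rec.numerator)
        if cur is None or (rec.p_discovery, rec.denominator) < \
                (cur.p_discovery, cur.denominator):
            best[rec.numerator] = rec
    deduped = [best[g] for g in sorted(best)]
    adj = naive_bh([r.p_discovery for r in deduped], m=len(deduped))
    for rec, a in zip(deduped, adj):
        rec.p_adj_discovery = a

    called = sorted((r for r in deduped if r.p_adj_discovery < discovery_alpha),
                    key=lambda r: (r.p_adj_discovery, r.numerator))

    # validation on the held-out cohort
    if val:
        testable = []
        for rec in called:
            if any(counts.loc[rec.denominator, s] == 0 for s in val):
                rec.unvalidatable = True
                rec.validated = False
                continue
            rec.ratios_validation = {
                s: counts.loc[rec.numerator, s] / counts.loc[rec.denominator, s]
                for s in val}
            rec.p_validation = naive_t_test(
                [rec.ratios_validation[s] for s in val_c],
                [rec.ratios_validation[s] for s in val_t])
            testable.append(rec)
        adj = naive_bh([r.p_validation for r in testable], m=len(called))
        for rec, a in zip(testable, adj):
            rec.p_adj_validation = a
            rec.validated = a < validation_alpha

    return {"candidates": candidates, "deduped": deduped, "called": called,
            "gene_p": gene_p}
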