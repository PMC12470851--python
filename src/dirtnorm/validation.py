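"""Independent-cohort validation and strict-DEG classification.

Discovery-called DiRTs are retested on a held-out cohort: the same
count ratio, the same equal-variance t-test, BH-adjusted with m equal
to the number of records entering validation (that is the family being
retested).  Genes backed by a validated DiRT are then screened for
*strict* differential expression: on the RLE-normalized scale the
treated-minus-control difference must carry the same nonzero sign in
every paired experiment across both cohorts (all nine pairs in a 5+4
design).  Finally each pair is typed: DEG–index (numerator responds,
denominator neutral), index–DEG, DEG–DEG (both respond — an artifact
class, flagged with whether the two regulations are opposite), or
unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .baselines import normalized_matrix, rle_size_factors
from .core import DiRTRecord, DirtParams
from .io import CountMatrix, SampleDesign
from .stats import _t_test_rows, bh_adjust


@dataclass
class StrictDegCall:
    """Direction-concordance record for one gene.

    ``per_pair_signs`` maps (cohort, pair_index) to the sign of the
    RLE-normalized treated-minus-control difference; ``direction`` is
    set only when every sign is the same and nonzero.
    """

    gene_id: str
    per_pair_signs: dict[tuple[str, int], int]
    direction: str | None  # "up" / "down" / None
    n_concordant_pairs: int

    @property
    def is_strict(self) -> bool:
        return self.direction is not None


def validate_dirts(
    called: Sequence[DiRTRecord],
    cm_validation: CountMatrix,
    design: SampleDesign,
    params: DirtParams,
) -> list[DiRTRecord]:
    """Retest called DiRTs on the validation cohort (in place).

    Sets ``ratio_values_validation``, ``p_validation`` and
    ``p_adj_validation`` (BH, m = number of records entering
    validation); flags ``validated`` (adjusted p < validation_alpha) and
    ``strictly_validated`` (adjusted p < strict_validation_alpha).
    Records whose denominator hits a zero validation count are flagged
    ``unvalidatable`` rather than dropped.  Discovery fields are never
    touched.
    """
    controls = design.samples(cohort="validation", condition="control")
    treated = design.samples(cohort="validation", condition="treated")
    if len(controls) < 2 or len(treated) < 2:
        raise ValueError("need >= 2 control and >= 2 treated validation samples")
    samples = design.samples(cohort="validation")
    for rec in called:
        for g in (rec.numerator, rec.denominator):
            if g not in cm_validation.counts.index:
                raise KeyError(f"gene {g!r} missing from validation matrix")
    sub = cm_validation.counts[samples].astype(float) + params.pseudocount
    testable: list[DiRTRecord] = []
    for rec in called:
        den = sub.loc[rec.denominator]
        if (den == 0).any():
            rec.unvalidatable = True
            rec.validated = False
            rec.strictly_validated = False
            continue
        rec.ratio_values_validation = sub.loc[rec.numerator] / den
        testable.append(rec)
    if testable:
        a = np.vstack([r.ratio_values_validation[controls].to_numpy(float)
                       for r in testable])
        b = np.vstack([r.ratio_values_validation[treated].to_numpy(float)
                       for r in testable])
        _, _, p = _t_test_rows(a, b)
        adj = bh_adjust(p, m=len(called))
        for rec, pi, ai in zip(testable, p, adj):
            rec.p_validation = float(pi)
            rec.p_adj_validation = float(ai)
            rec.validated = bool(ai < params.validation_alpha)
            rec.strictly_validated = bool(ai < params.strict_validation_alpha)
    return list(called)


def strict_deg_calls(
    cm_all: CountMatrix,
    design: SampleDesign,
    gene_ids: Sequence[str],
) -> list[StrictDegCall]:
    """Per-pair direction concordance on the RLE-normalized scale.

    Expression is normalized with RLE size factors computed across all
    samples of both cohorts (raw counts would conflate direction with
    library depth).  For every C_i/T_i pair, sign_i = sign(T_i − C_i);
    a gene is a strict DEG iff all signs agree and are nonzero.
    """
    pairs = design.pairs()
    if not pairs:
        raise ValueError("design defines no C/T pairs")
    design.check_against(cm_all)
    factors = rle_size_factors(cm_all)
    norm = normalized_matrix(cm_all, factors)
    calls = []
    for gene in gene_ids:
        if gene not in norm.index:
            raise KeyError(f"gene {gene!r} missing from matrix")
        signs: dict[tuple[str, int], int] = {}
        for ctrl, trt, cohort, idx in pairs:
            diff = norm.loc[gene, trt] - norm.loc[gene, ctrl]
            signs[(cohort, idx)] = int(np.sign(diff))
        vals = list(signs.values())
        strict = all(v == vals[0] for v in vals) and vals[0] != 0
        direction = None
        if strict:
            direction = "up" if vals[0] > 0 else "down"
        dominant = max(sum(v > 0 for v in vals), sum(v < 0 for v in vals))
        calls.append(
            StrictDegCall(
                gene_id=gene,
                per_pair_signs=signs,
                direction=direction,
                n_concordant_pairs=dominant,
            )
        )
    return calls


def classify_pair(
    record: DiRTRecord,
    per_gene_de: pd.DataFrame | Mapping[str, float],
    params: DirtParams,
) -> str:
    """Type a DiRT pair from per-gene DE evidence (discovery CPM t-tests).

    deg_index: numerator responsive, denominator neutral; index_deg the
    reverse; deg_deg both responsive (annotated with whether the two
    fold directions are opposite when direction data is available);
    unresolved: neither.  Sets ``record.pair_class`` and returns it.
    """
    if isinstance(per_gene_de, pd.DataFrame):
        pvals = per_gene_de["p"]
        lfc = per_gene_de["log2fc"] if "log2fc" in per_gene_de.columns else None
    else:
        pvals = per_gene_de
        lfc = None
    for g in (record.numerator, record.denominator):
        if g not in pvals:
            raise KeyError(f"no per-gene DE p-value for {g!r}")
    num_de = float(pvals[record.numerator]) < params.denom_de_alpha
    den_de = float(pvals[record.denominator]) < params.denom_de_alpha
    if num_de and not den_de:
        cls = "deg_index"
    elif den_de and not num_de:
        cls = "index_deg"
    elif num_de and den_de:
        cls = "deg_deg"
        if lfc is not None:
            record.opposite_regulation = bool(
                lfc[record.numerator] * lfc[record.denominator] < 0
            )
    else:
        cls = "unresolved"
    record.pair_class = cls
    return cls


def deg_gene_lists(
    validated: Sequence[DiRTRecord],
    strict: Sequence[StrictDegCall],
) -> dict[str, list[str]]:
    """Up/down gene lists: validated-DiRT genes that are strict DEGs.

    Genes appear once, split by direction; the lists are what a pathway
    enrichment service would consume.  Both the numerator and, when it
    is itself a strict DEG, the denominator are considered (an
    index–DEG pair carries its DEG in the denominator).
    """
    strict_by_gene = {c.gene_id: c for c in strict if c.is_strict}
    up: list[str] = []
    down: list[str] = []
    seen: set[str] = set()
    for rec in validated:
        if not rec.validated:
            continue
        for g in (rec.numerator, rec.denominator):
            call = strict_by_gene.get(g)
            if call is None or g in seen:
                continue
            seen.add(g)
            (up if call.direction == "up" else down).append(g)
    return {"up": sorted(up), "down": sorted(down)}


def strict_calls_to_frame(calls: Sequence[StrictDegCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"gene_id": c.gene_id, "direction": c.direction or "none",
               "n_concordant_pairs": c.n_concordant_pairs}
        for (cohort, idx), s in sorted(c.per_pair_signs.items()):
            row[f"sign_{cohort[:4]}_{idx}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
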