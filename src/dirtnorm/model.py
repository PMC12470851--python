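"""Model-style front end: ``DiRT(counts, design).fit()``.

The class wraps the functional pipeline the way a statistical modelling
package wraps an estimator: the model object holds the data and the
parameters, ``fit`` runs candidate selection, testing, filtering,
deduplication, adjustment, calling and (when a validation cohort is
present) validation plus strict-DEG classification, and the returned
results object carries every intermediate table with a ``summary()``.
"""

from __future__ import annotations

import pandas as pd

from . import core, validation as val
from .core import DirtParams, DiRTRecord, records_to_frame
from .io import CountMatrix, SampleDesign, abundance_filter, read_counts, read_design
from .validation import StrictDegCall, strict_calls_to_frame


class DiRT:
    """DEG-by-index ratio transformation analysis of a count matrix.

    Parameters
    ----------
    counts
        Raw gene × sample read counts (both cohorts' samples).
    design
        Condition / cohort / pairing labels for every sample.
    params
        Pipeline parameters; defaults follow the standard workflow
        (top 10,000 genes, 10 candidates per target, denominator screen
        at p 0.1, discovery and validation calls at adjusted p 0.05).
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: SampleDesign,
        params: DirtParams | None = None,
    ) -> None:
        design.check_against(counts)
        self.counts = counts
        self.design = design
        self.params = params or DirtParams()

    @classmethod
    def from_files(
        cls,
        counts_path: str,
        design_path: str,
        dialect: str = "plain",
        params: DirtParams | None = None,
    ) -> "DiRT":
        return cls(read_counts(counts_path, dialect=dialect),
                   read_design(design_path), params)

    def fit(self, validate: bool | None = None) -> "DiRTResults":
        """Run the full pipeline.

        ``validate=None`` validates exactly when the design contains a
        validation cohort.
        """
        p = self.params
        top_n = min(p.top_n_genes, self.counts.n_genes)
        filtered = abundance_filter(self.counts, self.design, top_n)
        candidates = core.select_index_candidates(filtered, self.design, p)
        db = core.build_candidate_db(filtered, self.design, candidates, p)
        core.test_dirts(db, self.design)
        per_gene_de = core.per_gene_cpm_tests(filtered, self.design)
        kept = core.denominator_deg_filter(db, filtered, self.design, p,
                                           per_gene_p=per_gene_de["p"])
        records = core.dedup_and_adjust(kept, p)
        called = core.call_dirts(records, p)

        has_validation = bool(self.design.samples(cohort="validation"))
        if validate is None:
            validate = has_validation
        strict: list[StrictDegCall] = []
        gene_lists = {"up": [], "down": []}
        if validate:
            if not has_validation:
                raise ValueError("design has no validation cohort")
            val.validate_dirts(called, filtered, self.design, p)
            for rec in called:
                val.classify_pair(rec, per_gene_de, p)
            validated = [r for r in called if r.validated]
            genes = sorted({g for r in validated
                            for g in (r.numerator, r.denominator)})
            if genes:
                strict = val.strict_deg_calls(filtered, self.design, genes)
                gene_lists = val.deg_gene_lists(called, strict)
        return DiRTResults(
            model=self,
            filtered_counts=filtered,
            candidates=candidates,
            candidate_db=db,
            records=records,
            called=called,
            per_gene_de=per_gene_de,
            strict_degs=strict,
            gene_lists=gene_lists,
            n_dropped_candidates=len(candidates) - len(db),
        )


class DiRTResults:
    """Fitted DiRT pipeline output.

    Attributes
    ----------
    candidates : list of CandidatePair
        All (target, index, NSD) candidates (k per target).
    candidate_db : list of DiRTRecord
        Materialized records before filtering.
    records : list of DiRTRecord
        Deduplicated records, one per target, BH-adjusted.
    called : list of DiRTRecord
        Records below the discovery threshold, validation fields filled
        when a validation cohort was fitted.
    per_gene_de : DataFrame
        Per-gene CPM t-tests (the denominator screen, also used for
        pair classification).
    strict_degs : list of StrictDegCall
    gene_lists : {"up": [...], "down": [...]}
    """

    def __init__(self, model, filtered_counts, candidates, candidate_db,
                 records, called, per_gene_de, strict_degs, gene_lists,
                 n_dropped_candidates):
        self.model = model
        self.filtered_counts = filtered_counts
        self.candidates = candidates
        self.candidate_db = candidate_db
        self.records = records
        self.called = called
        self.per_gene_de = per_gene_de
        self.strict_degs = strict_degs
        self.gene_lists = gene_lists
        self.n_dropped_candidates = n_dropped_candidates

    @property
    def n_validated(self) -> int:
        return sum(1 for r in self.called if r.validated)

    def to_frame(self) -> pd.DataFrame:
        """All deduplicated records as a flat table."""
        return records_to_frame(self.records)

    def called_frame(self) -> pd.DataFrame:
        return records_to_frame(self.called)

    def strict_frame(self) -> pd.DataFrame:
        return strict_calls_to_frame(self.strict_degs)

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "DiRT analysis summary",
            "=====================",
            f"genes after abundance filter : {self.filtered_counts.n_genes}",
            f"candidate pairs (k={p.k_candidates})         : {len(self.candidates)}",
            f"records in candidate DB      : {len(self.candidate_db)}"
            + (f"  ({self.n_dropped_candidates} dropped, zero denominator)"
               if self.n_dropped_candidates else ""),
            f"records after dedup          : {len(self.records)} (BH m = {len(self.records)})",
            f"called at adj p < {p.discovery_alpha:<4}       : {len(self.called)}",
        ]
        if any(r.validated is not None for r in self.called):
            n_strict_val = sum(1 for r in self.called if r.strictly_validated)
            n_unval = sum(1 for r in self.called if r.unvalidatable)
            lines += [
                f"validated at adj p < {p.validation_alpha:<4}    : {self.n_validated}",
                f"strictly validated (p < {p.strict_validation_alpha}): {n_strict_val}",
                f"unvalidatable (zero counts)  : {n_unval}",
                f"strict DEGs                  : "
                f"{sum(1 for c in self.strict_degs if c.is_strict)} "
                f"(up {len(self.gene_lists['up'])}, down {len(self.gene_lists['down'])})",
            ]
        if self.called:
            lines.append("")
            lines.append("top records (numerator/denominator, adj p):")
            for r in self.called[:10]:
                tail = ""
                if r.p_adj_validation is not None:
                    tail = f"  validation adj p = {r.p_adj_validation:.3g}"
                lines.append(
                    f"  {r.numerator}/{r.denominator}  "
                    f"adj p = {r.p_adj_discovery:.3g}{tail}"
                )
        return "\n".join(lines)
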