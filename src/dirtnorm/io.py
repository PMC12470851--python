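"""Count-matrix and sample-design I/O.

Read counts come either from a featureCounts output table (comment line,
six annotation columns, one column per aligned library) or from a plain
gene × sample TSV.  The sample design assigns each library a condition
(``control`` / ``treated``), a cohort (``discovery`` / ``validation``)
and a ``pair_index`` pairing each treated library with a control one
(C_i / T_i) within its cohort.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("control", "treated")
COHORTS = ("discovery", "validation")

_FEATURECOUNTS_ANNOT = ["Chr", "Start", "End", "Strand", "Length"]


class CountMatrixError(ValueError):
    """Raised for malformed count matrices or design tables."""


@dataclass
class CountMatrix:
    """A nonnegative integer gene × sample read-count table.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
        Values must be nonnegative integers (raw read counts, RC).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate gene ids: {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate sample ids: {dup[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CountMatrixError("counts must be numeric")
        if np.any(~np.isfinite(arr.astype(float))):
            raise CountMatrixError("counts contain non-finite values")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise CountMatrixError(
                "negative or non-integer count at gene "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        self.counts = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        missing = [g for g in gene_ids if g not in self.counts.index]
        if missing:
            raise CountMatrixError(f"genes not in matrix: {missing[:5]}")
        return CountMatrix(self.counts.loc[list(gene_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise CountMatrixError(f"samples not in matrix: {missing[:5]}")
        return CountMatrix(self.counts[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class SampleDesign:
    """Per-sample condition / cohort / pairing labels.

    The table must have columns ``sample_id``, ``condition``
    (control/treated), ``cohort`` (discovery/validation) and
    ``pair_index`` (1-based; within each cohort control and treated
    samples carry the same set of pair indices so they are pairable as
    C_i / T_i).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        req = {"sample_id", "condition", "cohort", "pair_index"}
        missing = req - set(self.table.columns)
        if missing:
            raise CountMatrixError(f"design table missing columns: {sorted(missing)}")
        t = self.table.reset_index(drop=True).copy()
        t["sample_id"] = t["sample_id"].astype(str)
        if t["sample_id"].duplicated().any():
            raise CountMatrixError("duplicate sample ids in design")
        bad_cond = set(t["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise CountMatrixError(f"unknown condition labels: {sorted(bad_cond)}")
        bad_coh = set(t["cohort"]) - set(COHORTS)
        if bad_coh:
            raise CountMatrixError(f"unknown cohort labels: {sorted(bad_coh)}")
        t["pair_index"] = t["pair_index"].astype(int)
        if (t["pair_index"] < 1).any():
            raise CountMatrixError("pair_index must be >= 1")
        for cohort in t["cohort"].unique():
            sub = t[t["cohort"] == cohort]
            ctrl = set(sub.loc[sub["condition"] == "control", "pair_index"])
            trt = set(sub.loc[sub["condition"] == "treated", "pair_index"])
            if ctrl != trt:
                raise CountMatrixError(
                    f"cohort {cohort!r}: control pair indices {sorted(ctrl)} "
                    f"!= treated pair indices {sorted(trt)}"
                )
        self.table = t

    def samples(self, cohort: str | None = None, condition: str | None = None) -> list[str]:
        """Sample ids matching the given cohort/condition, in table order."""
        t = self.table
        if cohort is not None:
            t = t[t["cohort"] == cohort]
        if condition is not None:
            t = t[t["condition"] == condition]
        return list(t["sample_id"])

    def pairs(self) -> list[tuple[str, str, str, int]]:
        """All (control_sample, treated_sample, cohort, pair_index) pairs.

        The union over cohorts enumerates the independent C_i / T_i
        experiments (nine in a 5+4 design).
        """
        out = []
        for cohort in COHORTS:
            sub = self.table[self.table["cohort"] == cohort]
            if sub.empty:
                continue
            ctrl = sub[sub["condition"] == "control"].set_index("pair_index")["sample_id"]
            trt = sub[sub["condition"] == "treated"].set_index("pair_index")["sample_id"]
            for idx in sorted(ctrl.index):
                out.append((ctrl[idx], trt[idx], cohort, int(idx)))
        return out

    def check_against(self, cm: CountMatrix) -> None:
        missing = [s for s in self.table["sample_id"] if s not in cm.counts.columns]
        if missing:
            raise CountMatrixError(f"design samples absent from count matrix: {missing}")


def _strip_path_header(name: str) -> str:
    """Reduce a path-like featureCounts sample header to a bare name."""
    base = os.path.basename(name.strip())
    for ext in (".bam", ".sam", ".cram"):
        if base.lower().endswith(ext):
            base = base[: -len(ext)]
    return base


def read_counts(path: str, dialect: str = "plain") -> CountMatrix:
    """Read a count matrix from ``path``.

    ``dialect='featurecounts'`` expects the featureCounts layout: one or
    more ``#``-prefixed comment lines, then a header starting with
    Geneid/Chr/Start/End/Strand/Length followed by one column per
    library (often BAM paths, reduced here to basenames).
    ``dialect='plain'`` expects a gene-id column followed by one column
    per sample.
    """
    if dialect not in ("plain", "featurecounts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise CountMatrixError(f"{path}: no sample columns found")
    if dialect == "featurecounts":
        expected = _FEATURECOUNTS_ANNOT
        present = [c for c in expected if c in df.columns]
        if len(present) != len(expected):
            raise CountMatrixError(
                f"{path}: not a featureCounts table (missing {set(expected) - set(present)})"
            )
        df = df.drop(columns=expected)
        df.columns = [df.columns[0]] + [_strip_path_header(c) for c in df.columns[1:]]
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str) -> None:
    """Write a plain gene × sample TSV (readable by ``read_counts``)."""
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_design(path: str) -> SampleDesign:
    """Read a sample-design TSV (sample_id, condition, cohort, pair_index)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return SampleDesign(pd.read_csv(path, sep="\t"))


def write_design(design: SampleDesign, path: str) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def library_sizes(cm: CountMatrix) -> pd.Series:
    """Per-sample total assigned reads (column sums); CPM denominators."""
    sizes = cm.counts.sum(axis=0)
    zero = sizes.index[sizes == 0].tolist()
    if zero:
        raise CountMatrixError(f"samples with zero total counts (CPM undefined): {zero}")
    return sizes


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million: RC / library size × 1e6 (no log, no pseudocount)."""
    sizes = library_sizes(cm)
    return cm.counts.div(sizes, axis=1) * 1e6


def abundance_filter(
    cm: CountMatrix, design: SampleDesign, top_n: int
) -> CountMatrix:
    """Keep the ``top_n`` most abundant genes.

    Abundance is the total raw count summed over the discovery-cohort
    samples (both conditions); ties broken by lexicographic gene id.
    The output is ordered by descending abundance, then gene id, and
    retains all samples of the input (validation columns are subset to
    the surviving genes).
    """
    if top_n > cm.n_genes:
        raise CountMatrixError(
            f"top_n={top_n} exceeds number of genes ({cm.n_genes})"
        )
    disc = design.samples(cohort="discovery")
    if not disc:
        raise CountMatrixError("no discovery samples in design")
    totals = cm.counts[disc].sum(axis=1)
    order = sorted(cm.gene_ids, key=lambda g: (-totals[g], g))
    return CountMatrix(cm.counts.loc[order[:top_n]])
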