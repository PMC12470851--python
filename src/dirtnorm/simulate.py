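"""Negative-binomial count simulator with co-expression modules.

The generator produces the statistical structure the ratio method
assumes and the failure mode it is designed to survive:

* per-gene baseline abundance drawn log-normally (wide dynamic range);
* co-expression modules — blocks of genes sharing a biological factor,
  so within-sample count ratios inside a module are stable (the source
  of good index genes); ``module_tightness`` sets the fraction of a
  gene's biological log-variation carried by the shared factor;
* biological variation placed at the *experiment* level by default: in
  a paired design each C_i/T_i pair comes from one experiment, and the
  dominant variation between independent experiments is shared by the
  pair's control and treated library.  This is what defeats global
  normalization (conditions differ wildly between experiments) while
  leaving within-sample ratios and within-pair sign comparisons clean.
  ``module_factor_level='sample'`` draws the factor independently per
  sample instead;
* library-depth variation (per-sample multiplicative factors);
* a compositional batch effect: whole modules inflated by a constant
  log2 amount in a chosen subset of samples (by default the
  discovery-cohort treated samples, the worst case for a two-condition
  design analyzed with global scaling);
* planted treatment effects: selected genes shifted by a constant log2
  fold change in every treated sample of both cohorts;
* negative-binomial sampling around the resulting mean with residual
  dispersion φ (variance μ + φμ²).  Biological variation is explicit
  in the factors above, so φ is the technical/unshared remainder, not
  the total replicate dispersion.

Everything is driven by one explicit seed; truth tables record planted
effects, module membership and batch-affected genes for recovery
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleDesign

DEFAULT_SEED = 20250827


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic count generator.

    Defaults define the standard recovery scenario: 2,000 genes, 40
    modules of 10, tightness 0.9, a 5v5 discovery and 4v4 validation
    design, 20 planted DEGs at |log2FC| = 1.5 (half up, half down), and
    a 2-fold batch inflation of whole modules covering 10% of genes in
    the discovery treated samples only.

    ``bio_sd`` is the standard deviation of the log-scale biological
    factor (0.8 ≈ 2.2-fold typical swings between independent
    experiments, the regime where global normalization breaks down);
    ``nb_dispersion`` is the residual NB overdispersion beyond those
    factors (0.01, near-technical).
    """

    n_genes: int = 2000
    n_control_discovery: int = 5
    n_treated_discovery: int = 5
    n_control_validation: int = 4
    n_treated_validation: int = 4
    base_abundance_meanlog: float = 6.5   # log expected counts
    base_abundance_sdlog: float = 1.2
    nb_dispersion: float = 0.01           # φ in var = μ + φμ²
    n_modules: int = 40
    module_size: int = 10
    module_tightness: float = 0.9
    bio_sd: float = 0.8                   # sd of module-level biological log-variation
    singleton_bio_sd: float = 0.25        # private log-sd of genes outside modules
    module_factor_level: str = "experiment"  # or "sample"
    library_factor_range: tuple[float, float] = (0.5, 1.5)
    batch_gene_fraction: float = 0.10
    batch_log2_magnitude: float = 1.0
    batch_samples: str | tuple[str, ...] = "discovery_treated"
    planted_degs: tuple[tuple[str, float], ...] | None = None
    n_planted_degs: int = 20
    planted_log2fc: float = 1.5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules cover more genes than exist")
        if not 0 <= self.module_tightness <= 1:
            raise ValueError("module_tightness must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.module_factor_level not in ("experiment", "sample"):
            raise ValueError("module_factor_level must be 'experiment' or 'sample'")
        lo, hi = self.library_factor_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_factor_range must be positive and ordered")
        if not 0 <= self.batch_gene_fraction <= 1:
            raise ValueError("batch_gene_fraction must lie in [0, 1]")
        if self.n_planted_degs < 0:
            raise ValueError("n_planted_degs must be >= 0")
        if self.bio_sd < 0 or self.singleton_bio_sd < 0:
            raise ValueError("biological noise sds must be >= 0")

    def null(self) -> "SimConfig":
        """The matching null scenario: no planted effects, no batch."""
        return replace(self, n_planted_degs=0, planted_degs=(),
                       batch_gene_fraction=0.0)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _make_design(cfg: SimConfig) -> SampleDesign:
    rows = []
    for i in range(1, cfg.n_control_discovery + 1):
        rows.append((f"C{i}", "control", "discovery", i))
    for i in range(1, cfg.n_treated_discovery + 1):
        rows.append((f"T{i}", "treated", "discovery", i))
    off_c = cfg.n_control_discovery
    off_t = cfg.n_treated_discovery
    for i in range(1, cfg.n_control_validation + 1):
        rows.append((f"C{off_c + i}", "control", "validation", i))
    for i in range(1, cfg.n_treated_validation + 1):
        rows.append((f"T{off_t + i}", "treated", "validation", i))
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "condition", "cohort", "pair_index"]))


def _batch_sample_mask(cfg: SimConfig, design: SampleDesign) -> np.ndarray:
    ids = design.table["sample_id"].tolist()
    if isinstance(cfg.batch_samples, str):
        if cfg.batch_samples == "discovery_treated":
            affected = set(design.samples(cohort="discovery", condition="treated"))
        elif cfg.batch_samples == "none":
            affected = set()
        else:
            raise ValueError(f"unknown batch_samples spec {cfg.batch_samples!r}")
    else:
        affected = set(cfg.batch_samples)
        unknown = affected - set(ids)
        if unknown:
            raise ValueError(f"batch samples not in design: {sorted(unknown)}")
    return np.array([s in affected for s in ids])


def simulate_counts(
    cfg: SimConfig,
) -> tuple[CountMatrix, SampleDesign, dict[str, pd.DataFrame]]:
    """Draw a count matrix, its design, and truth tables.

    For gene g and sample s the negative-binomial mean is

        μ_gs = base_g · lib_s · exp(τ·Z_{m(g),e(s)} + (1−τ)·ε_gs)
                        · 2^{Δ_g·treated(s)} · 2^{β·batch(g,s)}

    with τ the module tightness, Z the shared module factor (indexed by
    experiment e(s) — the C/T pair the sample belongs to — or by sample,
    per ``module_factor_level``), ε private biological noise (both
    N(0, bio_sd)), Δ the planted log2 fold change and β the batch log2
    magnitude.  Genes outside any module carry their full biological
    noise privately.  Counts are NB(μ, φ).

    Truth tables: ``planted`` (gene, log2fc), ``modules`` (gene,
    module; −1 for singletons), ``batch_genes`` (gene, module, log2).
    Batch-affected genes are whole modules, chosen at random until
    ``batch_gene_fraction`` of all genes is covered, and disjoint from
    modules hosting planted DEGs — the batch is a compositional block
    artifact, not a treatment effect.
    """
    rng = np.random.default_rng(cfg.seed)
    design = _make_design(cfg)
    genes = _gene_ids(cfg.n_genes)
    samples = design.table["sample_id"].tolist()
    n_s = len(samples)
    treated_mask = (design.table["condition"] == "treated").to_numpy()
    batch_mask = _batch_sample_mask(cfg, design)

    base = np.exp(rng.normal(cfg.base_abundance_meanlog,
                             cfg.base_abundance_sdlog, cfg.n_genes))
    lo, hi = cfg.library_factor_range
    lib = rng.uniform(lo, hi, n_s)

    # module membership: first n_modules*module_size genes of a random order
    module_of = np.full(cfg.n_genes, -1)
    perm = rng.permutation(cfg.n_genes)
    for m in range(cfg.n_modules):
        module_of[perm[m * cfg.module_size:(m + 1) * cfg.module_size]] = m

    # batch modules first, then planted DEGs in the remaining modules
    n_batch_genes = int(round(cfg.batch_gene_fraction * cfg.n_genes))
    module_order = rng.permutation(cfg.n_modules) if cfg.n_modules else np.array([], int)
    batch_modules: list[int] = []
    covered = 0
    for m in module_order:
        if covered >= n_batch_genes:
            break
        batch_modules.append(int(m))
        covered += cfg.module_size
    batch_gene_mask = np.isin(module_of, batch_modules) if batch_modules else \
        np.zeros(cfg.n_genes, bool)

    delta = np.zeros(cfg.n_genes)
    if cfg.planted_degs is not None:
        planted = [(g, float(f)) for g, f in cfg.planted_degs]
        idx_of = {g: i for i, g in enumerate(genes)}
        for g, f in planted:
            if g not in idx_of:
                raise ValueError(f"planted gene {g!r} not simulated")
            delta[idx_of[g]] = f
    else:
        free_modules = [m for m in range(cfg.n_modules) if m not in batch_modules]
        if cfg.n_planted_degs > len(free_modules):
            raise ValueError(
                f"cannot place {cfg.n_planted_degs} planted DEGs in "
                f"{len(free_modules)} non-batch modules (one per module)")
        host = rng.permutation(np.array(free_modules, int))[:cfg.n_planted_degs]
        planted = []
        for j, m in enumerate(host):
            members = np.flatnonzero(module_of == m)
            gi = int(rng.choice(members))
            fc = cfg.planted_log2fc if j % 2 == 0 else -cfg.planted_log2fc
            delta[gi] = fc
            planted.append((genes[gi], fc))

    # experiment index of each sample: its (cohort, pair_index) pair
    pair_key = list(zip(design.table["cohort"], design.table["pair_index"]))
    uniq = sorted(set(pair_key))
    exp_of = np.array([uniq.index(k) for k in pair_key])
    n_exp = len(uniq)

    tau = cfg.module_tightness
    n_units = n_exp if cfg.module_factor_level == "experiment" else n_s
    z = rng.normal(0.0, cfg.bio_sd, (max(cfg.n_modules, 1), n_units))
    eps = rng.normal(0.0, cfg.bio_sd, (cfg.n_genes, n_s))
    bio = (1 - tau) * eps
    in_module = module_of >= 0
    if cfg.n_modules:
        unit_of = exp_of if cfg.module_factor_level == "experiment" else np.arange(n_s)
        bio[in_module] += tau * z[module_of[in_module]][:, unit_of]
    # genes outside modules: moderate private noise (the dramatic
    # between-experiment swings live in co-regulated modules)
    bio[~in_module] = rng.normal(0.0, cfg.singleton_bio_sd,
                                 (int((~in_module).sum()), n_s))

    log2 = np.log(2.0)
    mu = (base[:, None] * lib[None, :] * np.exp(bio)
          * np.exp(log2 * delta[:, None] * treated_mask[None, :]))
    if batch_gene_mask.any():
        mu = mu * np.exp(log2 * cfg.batch_log2_magnitude
                         * batch_gene_mask[:, None] * batch_mask[None, :])

    r = 1.0 / cfg.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    truth = {
        "planted": pd.DataFrame(sorted(planted), columns=["gene_id", "log2fc"]),
        "modules": pd.DataFrame({"gene_id": genes, "module": module_of}),
        "batch_genes": pd.DataFrame(
            {"gene_id": [genes[i] for i in np.flatnonzero(batch_gene_mask)],
             "module": module_of[batch_gene_mask],
             "log2": cfg.batch_log2_magnitude}),
    }
    return cm, design, truth


def recovery_report(
    validated_records: Sequence,
    strict_calls: Sequence,
    truth: dict[str, pd.DataFrame],
) -> dict[str, float]:
    """Score pipeline output against the simulation truth.

    sensitivity: planted genes among the final calls (validated DiRTs
    whose gene is a strict DEG) over planted genes.  observed_fdr:
    non-planted among the final calls over all final calls (0 when the
    call set is empty).  index_from_module_rate: fraction of validated
    DiRTs whose index gene shares the numerator's module.
    """
    from .validation import deg_gene_lists  # local import avoids cycle

    planted = set(truth["planted"]["gene_id"])
    lists = deg_gene_lists(validated_records, strict_calls)
    called_genes = set(lists["up"]) | set(lists["down"])
    sensitivity = (len(called_genes & planted) / len(planted)) if planted else 0.0
    fdr = (len(called_genes - planted) / len(called_genes)) if called_genes else 0.0

    module_of = truth["modules"].set_index("gene_id")["module"]
    shared = 0
    n_val = 0
    for rec in validated_records:
        if not getattr(rec, "validated", False):
            continue
        n_val += 1
        mn = module_of.get(rec.numerator, -1)
        md = module_of.get(rec.denominator, -2)
        if mn >= 0 and mn == md:
            shared += 1
    rate = shared / n_val if n_val else 0.0
    return {
        "sensitivity": sensitivity,
        "observed_fdr": fdr,
        "index_from_module_rate": rate,
        "n_called_genes": float(len(called_genes)),
    }
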