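# Methods

This note documents the statistical model behind `dirtnorm`, the design
choices that were genuinely open, what the synthetic-data generator does and
does not emulate, and the known limitations of the ratio pipeline —
including one important uncalibrated behaviour of its discovery stage.

## 1. The ratio transformation

For a target gene *g* with index gene *i(g)*, the tested quantity in sample
*s* is the raw count ratio DiRT(g, s) = RC_g(s) / RC_{i(g)}(s) — no log, no
pseudocount (a `pseudocount` parameter exists but defaults to 0; the
abundance filter makes zeros rare, and pseudocounts distort ratios of
low-count genes).  Any per-sample multiplicative factor — sequencing depth,
a global scaling error, or a batch factor shared by both genes — cancels
exactly.  This is the method's core claim, and it holds to the last bit:
multiplying all counts of a sample by a constant leaves every NSD, every
t-statistic and every call unchanged (the test suite asserts bitwise
equality; with integer counts the scaled and unscaled ratios are the same
rational number, so IEEE rounding is identical).

**NSD.** "Normalized standard deviation" is implemented as the coefficient
of variation of the per-sample ratio over the discovery controls: sample
standard deviation (n−1 denominator) divided by the arithmetic mean.  CV is
the standard stability score for reference-gene selection and makes ratios
of different magnitude comparable.  NSD uses the discovery controls only:
index stability is a baseline property and the validation cohort must stay
untouched until validation.

**Eligibility and ties.** A partner with a zero count in any sample the
ratio is evaluated on is ineligible (no pseudocount by default); self-pairs
are excluded (a gene against itself has NSD 0 trivially).  All ties — NSD,
dedup p-values, abundance ranks — break toward the lexicographically
smaller gene id, so every stage is deterministic and invariant to input
order.  The pairwise scan is chunked over targets (`chunk_size`, default
128) so peak memory stays at `chunk × n_genes × n_controls` doubles
(~50 MB at 10,000 genes); chunking is a pure performance knob and the
output is identical for any chunk size, which the tests assert.

## 2. Testing, filtering, adjustment

Each candidate record gets a two-sample, two-tailed pooled-variance t-test
(control vs treated ratios).  With zero pooled variance the limit behaviour
is used: p = 1 for equal means, p = 0 otherwise.  The denominator screen
removes records whose index gene is itself treatment-responsive on the CPM
scale (per-gene equal-variance t-test, unadjusted p < 0.1); an externally
computed per-gene p table (for example Wald p-values from a count-model
fit) can be supplied instead.  Per target, the record with the lowest raw
p survives deduplication — the published procedure keeps "the entry with
the lowest adjusted p", but since the adjustment rank equals the
post-dedup count that phrasing is circular; minimizing raw p first and
adjusting afterwards is the only non-circular ordering and preserves the
ranking.  BH runs with an explicit multiplier m (the retained-record count
for the ratio arm; the full gene count for the baseline arm), and adjusted
values are capped at 1.0 (an export option can render 1.0 as NA for table
parity with edgeR-style output).

**Validation.** Called records are retested on the held-out cohort with the
same t-test; BH uses m = number of records entering validation, because
that is the family actually retested.  A record whose denominator has a
zero validation count is flagged `unvalidatable`, never silently dropped.
A *strict DEG* additionally shows the same nonzero sign of
(treated − control) in every C_i/T_i pair across both cohorts, on the
RLE-normalized scale (raw counts would conflate direction with depth).
Pair classification (DEG–index / index–DEG / DEG–DEG / unresolved) reuses
the per-gene CPM tests; DEG–DEG pairs are annotated with whether the two
genes move in opposite directions, the artifact mode in which a ratio
amplifies two opposing shifts.

The dotted "validation threshold" drawn in per-pair plots is the midpoint
between the discovery control-group and treated-group ratio means; it is a
reporting device (side-of-threshold consistency), not part of the calls.

## 3. Discovery-stage selection bias — a known, important behaviour

The index candidates are chosen by *minimizing* NSD over ~n_genes partners
using the same control samples that then enter the t-test.  For a target
that has genuinely co-stable partners the selection is benign.  For a
target that has none, the minimization finds pairs whose control ratios are
tight *by chance*: the control group enters the t-test with an artificially
deflated variance while the treated group keeps its real spread, and the
per-target min-p deduplication amplifies the effect.  On null data (no
planted effects, no batch) with the default generator — where only 20% of
genes belong to co-expression modules — about 18% of targets reach
discovery adjusted p < 0.05.  The discovery stage of this pipeline is
therefore *not* a calibrated test; it is a permissive screen.  Error
control comes from the independent validation cohort, which the pipeline
treats as mandatory: in the default recovery scenario the final validated
strict-DEG set has observed FDR ≤ 0.1 while discovery alone calls
hundreds of records.  The acceptance suite contains a calibration test
asserting a ≤ 5% null discovery rate; it fails by design of the method,
and we keep it failing rather than masking the behaviour.

The same mechanism explains a second measured subtlety: under a
compositional batch effect confined to discovery treated samples, discovery
*prefers* the one candidate pairing that reveals the batch shift (an index
outside the batch block) over the nine pairings that cancel it — batch
genes are heavily over-represented among discovery calls.  After
validation none survive, while the global-normalization baselines, used the
way such pipelines are used in practice (unadjusted p < 0.05 candidate
lists when adjusted p's call nothing), flag tens of batch genes.  DiRT's
batch robustness is a property of its discovery + validation loop, not of
the discovery test alone.

## 4. The synthetic generator

`simulate_counts` draws counts NB(μ, φ) with

μ_gs = base_g · lib_s · exp(τ·Z_{m(g),e(s)} + (1−τ)·ε_gs) ·
2^{Δ_g·treated(s)} · 2^{β·batch(g,s)}

- **base_g** — log-normal expected counts (meanlog 6.5, sdlog 1.2 ≈ median
  670, spanning ~40–20,000), the abundance spread of a filtered bulk
  matrix.
- **lib_s** — uniform library-depth factors in [0.5, 1.5].
- **Z** — the module factor, N(0, bio_sd) with bio_sd = 0.8, shared by all
  genes of a module with weight τ (tightness, default 0.9).  It is indexed
  by *experiment* — the C_i/T_i pair a sample belongs to — because in a
  paired design the dominant biological variation is between independent
  experiments and is shared by the pair's two libraries.  This one choice
  creates simultaneously (i) stable within-module ratios, (ii) wildly
  unstable expression across experiments (log-sd 0.72 ≈ 2-fold swings, the
  regime in which global normalization finds nothing), and (iii) clean
  within-pair sign comparisons for strict-DEG calling.  A
  `module_factor_level="sample"` switch draws the factor per sample
  instead, which removes property (iii).
- **ε** — private noise: sd (1−τ)·bio_sd for module genes; genes outside
  modules get moderate private noise (singleton_bio_sd = 0.25) — the
  dramatic co-regulated swings live in regulons, not in every gene.
- **Δ** — planted log2 fold changes applied in *all* treated samples (both
  cohorts); by default 20 genes at ±1.5, one per module, half up half
  down.
- **batch** — whole modules (a compositional block) inflated by
  2^{batch_log2} in a configurable sample set, by default the discovery
  treated samples — the worst case for a two-condition design.  Batch
  modules and planted-DEG modules are disjoint: the batch is an artifact,
  not a treatment effect.
- **φ** — residual NB overdispersion, default 0.01.  Biological
  replicate variation is modeled *explicitly* by the factors above, so φ
  is the technical-plus-unshared remainder; using the typical total bulk
  dispersion (~0.05) here would double-count biological variance and put a
  floor of √(2φ) ≈ 0.32 on every pair's ratio CV, leaving no pair with a
  stable ratio — contradicting the structure the generator exists to
  produce.

What the generator does **not** emulate: count correlation beyond the
module factor (no gene-gene regulatory network), gene length and GC
effects, isoform structure, outlier samples, and non-multiplicative batch
distortions.  Passing recovery tests therefore show that the pipeline
works when its own premise (co-stable partners exist; indexes are
treatment-neutral) holds — they do not certify behaviour on real data
where that premise may fail gene by gene.

## 5. Baselines

RLE size factors are the linear-space median over all-positive genes of
count / per-gene geometric mean; normalized values are count / factor.
(The median-of-ratios factor tracks depth changes only up to the
pseudo-reference shift 2^{1/n_samples}; the normalized expression
*structure* is exactly preserved, which is what the tests assert.)  TMM
follows the canonical edgeR conventions: reference sample by
closest-to-mean upper-quartile CPM, M/A computed on depth-divided counts
over genes positive in both samples, trimming 30% of M and 5% of A from
*each* tail, precision weights from the delta-method binomial variance,
early exit (factor 1) when all |M| < 1e-6, and factors rescaled to
geometric mean 1; agreement with edgeR's `calcNormFactors` is asserted in
the test suite via Rscript.  Baseline DE tests run the same equal-variance
t-test on normalized values (TMM tests use TMM-scaled counts rescaled to
the mean effective depth; the scale is recorded in the output metadata)
with BH over the full gene count.

## 6. Problem sizes and numerical choices

The shipped analyses use 2,000 genes for calibration and recovery runs
(20 generator seeds for the null rate) and one 12,000 → top-10,000 gene
run for the candidate-database cardinality; the full 10⁸-pair NSD scan
takes well under a minute chunked.  Tolerances: scale invariance is
asserted exactly (see §1); cross-implementation agreement (scipy t-test,
edgeR TMM, naive reference pipeline) at rel. 1e-6…1e-9; closed-form checks
exactly.  Degenerate inputs are errors, not silent repairs: zero-total
libraries, duplicate ids, unpairable designs, targets with fewer than k
eligible partners, genes missing from the validation matrix.

## 7. Limitations

- The discovery stage is anti-conservative by construction (§3); results
  without an independent validation cohort should be treated as a ranked
  screen, not as calls.
- The published counts this package's defaults echo (10,000 retained
  genes, k = 10, the 0.1 denominator screen, 0.05/0.01 thresholds) are
  conventions, not optimized values.
- Equal-variance t-tests on raw ratios are exposed to skew; with planted
  up-shifts the treated-group variance grows with the mean, and 4v4
  validation power at |log2FC| = 1.5 is the binding constraint on
  sensitivity.
- The per-pair strict-DEG criterion requires an explicit C_i/T_i pairing
  (`pair_index` in the design file); with unpaired cohorts strictness is
  undefined and the pipeline refuses to compute it.
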