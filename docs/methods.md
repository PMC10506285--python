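# Methods

This note documents the models, numerical choices and limitations behind
`spotlink`: what each stage computes, which parameters matter and why their
defaults are what they are, what the synthetic-tissue generator does and
does not emulate, and where the design was genuinely open.

## Data model and geometry

A dataset is a genes × spots integer count matrix with per-spot array
coordinates, sample identity, response-group label, and (once annotated)
cluster and compartment labels. Compartments are merged cluster categories
in {tumor, immune, CAF, other}; merging many fine-grained clusters into a
few compartments is how composition is compared across samples.

The hexagonal dialect fixes (array_row + array_col) even as the valid
parity, with neighbor offsets (0, ±2) and (±1, ±1). Adjacency is computed
strictly within a sample — tissue sections from different patients share no
physical boundary, and the interaction analysis is run per patient. Two
clusters count as spatially adjacent when they share at least
`min_contact_edges = 10` boundary edges. No quantitative definition of
"direct contact" exists upstream; the floor of 10 suppresses
single-spot-contact artifacts and is exposed in the configuration.

## Normalization

Counts are normalized as log2(1 + 10⁴·count/spot_total) (log-CPM at scale
10⁴). Every downstream statistic — Pearson/Spearman correlations, module
means, AUC ranks — needs only a monotone, roughly variance-stabilized
scale, so a regression-based variance-stabilizing transform would add a
fitted model without changing any rank- or correlation-based result
qualitatively. This is a deliberate divergence from pipelines that use
SCTransform-style normalization; it keeps the stage dependency-free and
exactly reproducible.

Genes detected in fewer than 2.5% of spots are excluded
(`min_spot_fraction = 0.025`, boundary inclusive: exactly 2.5% is kept).
By default this filter is applied within the analysis region of the
signaling stage (matching its position in the protocol it implements);
a switch applies it globally instead. The spot-level QC floor
(`min_counts = 250`) is not a published value — upstream work removed
low-quality spots by histology — and is a configuration choice.

## Pseudo-bulk differential expression

Spots of one compartment are summed per sample into pseudo-bulk libraries;
one library per patient per compartment (the plausible alternative,
patient × cluster units, is not the default because it multiplies
non-independent libraries per patient). Inference needs ≥ 2 samples per
group.

The test is a self-contained negative-binomial Wald pipeline in the DESeq2
tradition, not a wrapper around it:

- size factors by median-of-ratios (reference = per-gene geometric mean
  over samples, genes with any zero excluded from the reference);
- per-gene dispersion by method of moments on normalized counts, clipped
  to [1e-8, 10], then shrunk 50/50 in log space toward a fitted
  `α(μ) = a₀ + a₁/μ` trend (non-negative least squares coefficients);
- group means of normalized counts with a pseudo-count of 0.5 before the
  ratio, giving `log2fc = log2((m_A + ½)/(m_B + ½))`;
- delta-method standard error under `Var(y_j) = μ/s_j + αμ²`, two-sided
  normal Wald p-values, BH adjustment across all tested genes (genes
  dropped by the detection filter never enter the BH denominator).

There is no LFC shrinkage, no independent filtering, no outlier
refitting. Exact numerical agreement with any external tool is explicitly
not a contract; the test surface is calibration (empirical type-I error at
the nominal 5% level on a null cohort) and recovery (median estimated
log2FC within ±0.3 of a planted ±2 effect, sensitivity ≥ 0.8 at
padj ≤ 0.01). Both are verified in the suite and recomputed by
`scripts/acceptance.py`.

DE calls require |log2fc| ≥ 2 **and** padj ≤ 0.01. Ties in p-value are
broken by |Wald statistic| then gene id, so output order is deterministic.

## Preranked enrichment

The ranking metric is the DE log2 fold change (a signed −log10 p
alternative sits behind a flag). Genes are sorted descending with ties
broken by gene id. The running sum gains |score|/Σ|score in set| on set
members and loses 1/(N−m) on non-members; the enrichment score is the
extremum by absolute value. The null is gene-label permutation (random
re-placement of the set in the ranking) — the input is a preranked list,
so phenotype permutation is not available. p-values and NES are computed
within sign-matched null pools (p floored at 1/(n_perm+1)); a set whose
sign pool is empty gets NES = NaN and is flagged rather than dropped.
Sets with fewer than 5 genes in the ranking are skipped with a warning.
The weighting exponent (1) and the permutation scheme follow the classic
preranked algorithm; the upstream protocol does not state its choices, so
these defaults are documented as such.

## Regulons and per-spot activity

Co-expression importance is, by default, the absolute Spearman correlation
between a TF's normalized expression and every other gene across spots.
The role of this number is only to *rank* candidate targets; a
gradient-boosting importance (as in SCENIC's GRNBoost2 step) is one such
ranking, and an optional `spearman+forest` mode augments the correlation
with a seeded extremely-randomized-trees importance for users who want a
non-monotone measure. Targets strictly above the TF's 95th-percentile
importance are retained. The percentile is per-TF by default; whether the
upstream rule was per-TF or global is ambiguous, so a switch provides the
global pooled variant. Motif-based pruning is replaced by an optional
offline TF→allowed-target prior table (no motif databases are bundled);
with a prior, targets outside it are removed before the size rule.
Modules with fewer than 20 genes are discarded.

Activity scoring ranks each spot's genes by descending normalized
expression, with ties broken by one seeded random gene permutation per run
(reproducible, no systematic index bias). With k = ⌈0.05·N⌉, the recovery
curve counts module genes within the top i ranks for i = 1..k; the score
is the summed curve divided by its best achievable value (all module genes
at the very top), hence exactly in [0, 1], invariant to any monotone
transform of a spot's expression profile, and equal to a brute-force
step-curve integration (asserted exactly in the suite). The top fraction
0.05 is the conventional default of AUC-based module scoring and is
configurable.

## Signaling networks

For each sample and each adjacent cluster pair, in both sender→receiver
orientations:

1. the region is the union of the two clusters (a receiver-only mode
   exists behind a flag; the union matches "subset clusters to define
   spatial regions");
2. the 2.5% detection filter is applied within the region;
3. module activity (raw AUC scores — only receptor expression is z-scaled,
   following the protocol literally) is Pearson-correlated with z-scaled
   receptor expression over region spots; regions under 10 spots are
   refused, zero-variance receptors are recorded as r = 0 and flagged;
4. correlations are set to exactly 0 where the receptor is a target of
   the module's TF (otherwise a TF that simply upregulates its receptor
   would look like signaling);
5. links require r > 0.3 strictly;
6. a link survives only if some ligand–receptor record lists the receptor
   and at least one cognate ligand is detected in ≥ 5% of sender-cluster
   spots. Multi-subunit complexes are read conservatively: every subunit
   must individually pass. The 5% sender-side ligand floor
   (`ligand_expr_fraction`) is this package's choice — the upstream rule
   stated no ligand-detection threshold beyond the global gene filter —
   and is configurable.

Every emitted edge is re-validated against rules 3–6 at run time; the
suite additionally checks that raising the correlation threshold never
adds edges.

## Signature scoring and proportion correlation

A signature's module score is the plain arithmetic mean of normalized
expression over its genes present in the data ("averaged expression");
an expression-bin-matched background-corrected variant (24 bins, seeded
control draws) is opt-in. Region contrasts use the two-sided Wilcoxon
rank-sum test per signature with BH across signatures — the exact
enumeration when both regions have ≤ 10 spots and no ties, the normal
approximation otherwise. The upstream work reports regional significance
without naming a test; rank-sum is the assumption, documented here.

Association between signature-gene expression and deconvolved cell-type
proportions uses Spearman correlation with average-rank tie handling over
the common samples of the two tables (≥ 5 required), p-values by the t
approximation.

The packaged stemness (cancer stem cell) signature retains the printed
gene list verbatim; two entries (`SP`, `YY1A1`) are not resolvable
standard gene symbols and are excluded from scoring by default with a loud
warning rather than silently remapped (`include_ambiguous=True` keeps
them). `NOTCH` and `IL8` are likewise non-current symbols but are
unambiguous enough to keep.

## The synthetic-tissue generator

The generator emulates the statistical structure the pipeline must
resolve, with explicit truth for scoring:

- **Cohort**: 4 vs 3 samples by default, mirroring a small two-arm
  surgical series; each sample is a 50 × 80 hexagonal patch (2000 spots).
- **Domains**: five contiguous domains (tumor_A, tumor_B, immune, CAF,
  other) grown by quota-limited multi-source breadth-first growth from
  spaced seeds, guaranteeing contiguity and tumor–immune / tumor–CAF
  adjacency; planted sender/receiver pairs are verified adjacent.
- **Counts**: negative binomial with gene-level dispersion drawn
  log-normal (meanlog = log 0.15, sdlog = 0.5 — a typical UMI range),
  per-spot depth log-normal with CV 0.3 around 8000 (so the normalization
  path matters), gene baseline abundances log-normal.
- **Regulons**: each planted regulon ties its 30 targets, its TF and its
  receptor to a smooth latent field over the receiver domain: i.i.d.
  Gaussian noise, 3 neighbor-averaging sweeps on the domain subgraph,
  standardized, clipped at ±3, halved. Fields of regulons sharing a
  receiver domain are orthogonalized so each receptor tracks its own
  module rather than a domain-level mean shift; the field is mean-zero
  within the domain for the same reason. Loadings (targets 1.5, receptor
  2.4 on the natural-log scale) were calibrated once so the realized
  receptor–module correlation over an analysis region lands near the 0.6
  design coupling recorded in the truth (the AUC transform and NB noise
  cap what is achievable; realized values are ≈ 0.4–0.55).
- **Ligands**: each planted cognate ligand is elevated (+1.5 ln) only in
  its sender domain; decoy ligand/receptor pairs are expressed
  domain-flat, so only the correlation rules — never mere absence — can
  exclude decoys.
- **Cohort effects**: planted DE genes carry a ±2 log2 group effect; two
  signatures (stemness-like in tumor_B, immune in the immune domain) are
  localized sub-regionally.

What it does **not** emulate: within-spot cell-type mixtures (each spot
has one domain label; deconvolution is out of scope), segmentation or
doublet artifacts, batch effects between samples, sample-level biological
variability beyond the planted effects, mitochondrial/ribosomal content,
and any imaging component. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under a clean generative model,
not robustness to every artifact of real tissue. Effect sizes are chosen
for testability: real regulon–receptor couplings are not quantified in the
source material.

Determinism: one root seed drives everything; per-stage seeds derive from
it by a fixed FNV-style labeling scheme, and regenerating with the same
seed reproduces counts bit for bit (asserted in the suite).

## Problem sizes

The test suite and the acceptance script run the signaling chain on a
two-sample cohort (one per group, 2000 spots each — the per-sample size of
the default conditions), DE calibration on a 6 vs 6 cohort with 2000 genes
and ~200 spots per sample, and oracle comparisons at N = 500 genes × 240
instances (AUC) and 50 toy rankings (enrichment). These sizes give stable
statistics (binomial SE on the calibration fraction ≈ 0.5%) while keeping
the whole suite under a minute of simulation time.

## Known limitations

- The NB Wald test is calibrated under the generator's assumptions
  (shared dispersion structure, no sample-level random effects); strongly
  overdispersed real cohorts may need the trend-shrinkage weights
  revisited.
- Signaling correlations over union regions conflate within-domain
  covariation with between-domain contrast; the receiver-only flag
  isolates the former at reduced power.
- The gene-label permutation null for enrichment ignores inter-gene
  correlation, as all preranked permutation schemes do.
- Cluster labels are inputs: the PCA+k-means helper is a smoke-test
  utility, not a replacement for a real clustering and review workflow.
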