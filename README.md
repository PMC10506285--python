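# spotlink

Spatial-transcriptomics signaling analysis for Visium-style spot data, built
around the question of how neighboring cell populations in a tumor talk to
each other. Given spot-level counts with cluster/compartment annotation,
`spotlink` quantifies compartment composition, runs pseudo-bulk two-group
differential expression, preranked gene-set enrichment, transcription-factor
(TF) regulatory-module activity scoring per spot, and reconstructs
ligand→receptor→TF-module signaling networks between spatially adjacent
clusters. A synthetic hexagonal-tissue generator with planted ground truth
(regulons, signaling links, fold changes, localized signatures) makes every
stage testable end to end.

It is aimed at computational biologists analyzing tumor-microenvironment
spatial data — the motivating setting is hepatocellular carcinoma under
combined anti-angiogenic/checkpoint-inhibitor therapy, where responder and
non-responder tissues differ in immune/CAF composition and in
cancer–immune/cancer–CAF signaling.

## The method

**Geometry.** Spots live on the Visium hexagonal array: valid positions
satisfy (array_row + array_col) even, and spots are neighbors iff their
offset is (0, ±2) or (±1, ±1) within one sample. Two clusters are "in
direct contact" when they share at least `min_contact_edges` (default 10)
neighboring-spot pairs.

**Pseudo-bulk DE.** Spots of one compartment are summed per sample, giving
bulk-like libraries `K_gj`. The model is `K_gj ~ NB(s_j q_g,group(j),
α_g)` with median-of-ratios size factors `s_j`, method-of-moments
dispersion `α_g` shrunk 50/50 in log space toward a `α(μ) = a₀ + a₁/μ`
trend, a Wald test on `log2(q_A/q_B)`, and Benjamini–Hochberg adjustment.
A gene is called differentially expressed when |log2FC| ≥ 2 and adjusted
p ≤ 0.01.

**Enrichment.** Genes are ranked by log2 fold change; the classic weighted
running sum (weight exponent 1) gives the enrichment score, with a
gene-label permutation null for p, NES, and FDR.

**Regulons and activity.** For each TF, every expressed gene receives a
co-expression importance (absolute Spearman correlation by default);
targets above the TF's 95th-percentile importance form its module,
optionally pruned by a TF→target prior; modules with < 20 genes are
discarded. Per-spot activity is the area under the module's gene-recovery
curve within the top 5% of that spot's expression ranking, normalized to
[0, 1].

**Signaling networks.** Per sample and per adjacent cluster pair: subset
the region, drop genes detected in < 2.5% of region spots, correlate each
module's activity with z-scaled receptor expression over region spots,
zero any receptor targeted by the module's own TF, keep links with Pearson
r > 0.3 strictly, and require a cognate ligand (from a CellphoneDB-style
reference) detected in ≥ 5% of sender-cluster spots. Each surviving
(ligand, receptor, TF-module) triple is one directed edge.

## Worked example

Run the whole pipeline on the default simulated cohort (4 "responder" vs 3
"non-responder" samples, 2000 spots each, 8 planted signaling links, 40
decoy receptors):

```bash
spotlink run --seed 7 --out demo_run
```

or from Python:

```python
from spotlink.pipeline import run_pipeline
manifest = run_pipeline("demo_run", seed=7)
```

Selected outputs from that run:

```
$ cat demo_run/network_recovery.json
{"precision": 1.0, "recall": 1.0, "n_edges": 320}

$ cat demo_run/de_summary.json
{"n_up_A": 11, "n_up_B": 15, "n_tested": 1500}

```

and the first rows of `demo_run/gsea_results.tsv` (rounded to 3 digits):

| set | es | nes | pvalue |
| --- | --- | --- | --- |
| CSC_LIKE | 0.241 | 0.416 | 0.925 |
| IMMUNE_ACTIVATION | -0.241 | -0.402 | 0.934 |
| PLANTED_UP_A | 1.000 | 1.668 | 0.002 |
| PLANTED_UP_B | -1.000 | -1.746 | 0.002 |

`network_recovery.json` scores the reconstructed ligand→receptor→TF edges
against the planted truth: here all 8 planted (receptor, TF) links are
recovered across samples with no false links (precision and recall 1.0;
320 edges because each link appears per sample, per adjacent pair and per
orientation). The DE summary counts genes passing |log2FC| ≥ 2 and
padj ≤ 0.01; planted fold changes sit exactly at the ±2 boundary, so
roughly half of the 60 planted genes clear the fold-change bound in any
one run while essentially all are significant by padj alone. In the
enrichment table the two spatially-localized signatures (stemness-like,
immune) are not group-differential — they separate regions, not cohorts —
while the planted group-level sets reach enrichment scores of ±1.0 with
permutation p ≈ 0.002.

Per-stage subcommands (`spotlink simulate / preprocess / de / gsea /
regulons / signaling / score / corr`) expose the same steps on files you
provide; `spotlink run` writes a `manifest.json` with content hashes of
every output, reproducible given the same seed.

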