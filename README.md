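# nephrosens

Cortex-vs-medulla metabolic sensitivity analysis for untargeted metabolomics
of cisplatin nephrotoxicity — a tested, reusable reimplementation of the
full post-processing pipeline: QC and normalization of intensity matrices,
OPLS-DA differential-metabolite screening, and four independent
tissue-sensitivity comparisons, exercised end-to-end on a synthetic-data
generator with known dose-response ground truth.

## Who this is for

Metabolomics analysts comparing how strongly two tissue compartments (or any
two sample strata) respond to a graded exposure — here, rat kidney cortex vs
medulla after a single cisplatin dose (0, 2.5, 5 or 10 mg/kg; groups C, L,
M, H) — starting from a sample × feature peak-intensity table rather than
raw spectra.

## The methods

- **MSTUS normalization** — each sample is divided by its total useful
  signal, the summed intensity over features detected in every sample.
- **Quality control** — PCA of pooled-QC and study samples (R²X and row-wise
  cross-validated Q² per component), within-group relative log abundance
  (RLA) boxplot statistics, and retention-time variation of QC injections.
- **Differential screen** — per control-vs-dose OPLS-DA, a feature is
  differential when VIP > 1.0, the jackknife confidence interval on VIP is
  positive, and the Benjamini–Hochberg-adjusted Wilcoxon–Mann–Whitney
  p-value is below 0.05. A Venn partition splits each tissue's hits into
  common and tissue-specific metabolites.
- **Sensitivity comparisons** —
  1. *Random-forest error-rate ensemble*: for each control-vs-dose pair,
     1000 forests (ntree ∈ {500, 1000} × mtry ∈ {p/5, p/4, p/3, 2p/5} × 125
     stratified 2/3–1/3 resamples) record the test-set error rate (ERT);
     higher ERT = groups harder to separate = less sensitive tissue.
  2. *Matched-component Q²*: cross-validated Q² = 1 − PRESS/SS of
     control-vs-dose OPLS-DA models with identical component counts.
  3. *MCFC*: per treated sample, the metabolic cumulative fold change
     Σⱼ max(xⱼ/cⱼ, cⱼ/xⱼ) over the common metabolites (fold changes below 1
     enter as reciprocals), compared between tissues by Mann–Whitney U.
  4. *Two-step CAST*: cluster-affinity-search-technique clustering of
     per-metabolite log₂ fold-change profiles at Pearson r ≥ 0.80, keeping
     the up- and down-trend clusters, then re-clustering at r ≥ 0.98 and
     labelling each sub-cluster with a dose-response archetype
     (dose-monotone, step at M, step at H, uncorrelated). The contributive
     set is the medulla members of dose-monotone and step-M sub-clusters.

Everything is exposed both as sklearn-style estimators (`OPLSDA`,
`MSTUSNormalizer`, `CASTClustering`) and as plain functions, plus a
`nephrosens` command-line interface.

## Worked example

Simulate a two-tissue study at the original design (13/11/13/16 animals per
group, pooled QCs) and run the whole pipeline:

```bash
$ nephrosens simulate --n-features 100 --archetype-count 5 --seed 7 --out demo
wrote demo.csv (122 samples x 100 features) and demo.truth.json

$ nephrosens run-all --seed 7 --out demo_report
{
 "output_dir": "demo_report",
 "venn": {
  "common": 25,
  "a_only": 27,
  "b_only": 27
 },
 "cast": {
  "t1": 0.8,
  "t2": 0.98,
  "n_up": 20,
  "n_down": 56,
  "n_excluded": 28,
  ...
 }
}
```

The Venn block says 25 metabolites were screened as differential in both
tissues and 27 in each tissue alone (the generator plants 40 regulated
features per tissue, assigned independently, so partial overlap is
expected). The CAST block reports the two kept trend clusters (20 up, 56
down here), the 28 poorly dose-correlated profiles excluded at step 1, and
per-sub-cluster archetype labels. `demo_report/report.json` carries the full
bundle — PCA/RLA QC statistics, per-feature screen records, 1000 ERT
records per comparison, the matched-component Q² table (e.g. cortex C vs L:
Q² = 0.960 on this synthetic run), per-sample MCFC values with
between-tissue Mann–Whitney p-values, and heat-map/dendrogram data — all as
tidy CSV/JSON keyed by the config hash and seed.

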