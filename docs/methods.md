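# Methods

This note documents the models, defaults and numerical choices behind
`nephrosens`, and what the synthetic-data experiments do and do not show.

## Study design emulated by the generator

The generator (`nephrosens.simulate`) emulates a single-dose cisplatin
nephrotoxicity study in rats: a control group and three dose groups
(2.5 / 5 / 10 mg/kg — groups C, L, M, H) with **final** per-group animal
counts 13 / 11 / 13 / 16 (attrition is not simulated; the sizes are the
surviving cohorts), two kidney compartments (cortex, medulla) sharing
metabolite identities but with independently assigned regulation, and
pooled-QC injections (default 8 per tissue).

Abundances are strictly positive and log-normal: feature *j* in group *g*
has expected intensity `baseline_j × FC_j(g)`, with baselines drawn
log-normally around 10⁵ (spread `baseline_cv`, default 0.5) and
multiplicative log-normal measurement noise (`noise_cv`, default 0.1 —
mid-range for well-behaved MS features; QC noise defaults to 0.05).
Multiplicative noise keeps MSTUS normalization and reciprocal fold changes
well defined.

### Dose-response archetypes

Each regulated feature follows one archetype, in an up or a down variant:

| archetype | log₂ FC at (L, M, H) for effect *e* |
|---|---|
| `dose_monotone` | (e/3, 2e/3, e) |
| `step_M` | (0, e, e) |
| `step_H` | (0, 0, e) |
| `uncorrelated` | independent draws, rejected if \|r\| with the dose trend > 0.6 |

The monotone shape is linear in log dose: the three doses are equally
spaced on the log scale, so "fold changes gradually increasing with dose"
translates to equally spaced log₂ fold-change steps. Step archetypes jitter
each component by ±5% (their "≈1" and "≈ equal" slots become realistic
near-ties for the fine clustering step); the monotone archetype has no
approximate slots and keeps its nominal triple. The `uncorrelated`
archetype rejection-samples its log₂ triple so that it honours its name —
without the rejection, random triples are monotone-ish often enough to
contaminate trend clusters with mislabelled truth.

The default maximal effect is `log2_effect = 2` (a 4-fold change at the
high dose); the parameter-recovery experiments run at the boundary
`log2_effect = 1`. No public effect-size table exists for this study type
at feature level, so these defaults are chosen for testability and
plausibility, not fidelity to a particular dataset.

## Normalization and QC

**MSTUS.** The "useful" set is the features with strictly positive
intensity in every real (non-QC) sample — the published convention. Each
sample is divided by its useful-signal sum and rescaled by the median sum,
keeping magnitudes interpretable; the operation is idempotent and removes
per-sample scale exactly. *Known limitation:* MSTUS assumes differential
features contribute a small share of total signal. If a large fraction of
the signal is regulated (as in aggressive simulations), normalization
converts flat features into genuine relative changes; the recovery
experiments therefore plant 40 regulated features among 300 (≈2.5% shift in
total signal at the strongest dose).

**RLA.** Natural-log intensities minus the per-feature within-group (or
across-group) median; zeros are replaced by half the minimum positive value
beforehand. The within-group per-feature median of the output is exactly
zero by construction, which the tests assert literally.

**PCA.** Exact SVD solution after centering and scaling (unit-variance by
default — the common metabolomics convention; Pareto by flag). Q² per
component is estimated by row-wise 7-fold cross-validation: held-out rows
are reconstructed by projection onto the loadings fitted without them, and
Q²(a) = 1 − PRESS(a)/SS. Commercial chemometrics packages use a
proprietary element-wise scheme; values are comparable, not bit-identical.

**Feature collapsing.** Features within 0.05 min retention time whose
profiles correlate at r ≥ 0.9 (both configurable) merge to the
highest-mean-intensity representative via union-find — a coarse stand-in
for adduct/isotope/fragment grouping.

## OPLS-DA

NIPALS-based, deterministic (Y-side start, convergence tolerance 1e-10,
max 500 iterations). Binary problems use a single 0/1 indicator column;
multi-class problems use a one-hot indicator with `n_classes − 1`
predictive components by convention. Orthogonal components are extracted
against a fixed basis of the class-predictive weight space computed from
the undeflated matrix; for a single response this reproduces the classical
single-block algorithm exactly, and the fitted predictions of a
1-predictive + k-orthogonal model coincide with a (k+1)-component PLS
regression to machine precision (asserted against scikit-learn's PLS as an
independent oracle).

**VIP** is computed over all modelled components as
`VIP_j = sqrt(p · Σ_a SSY_a w²_aj / Σ_a SSY_a)` with normalized weights, so
ΣVIP² = p exactly (asserted on every fit); orthogonal components carry
(near-)zero explained class variance and so contribute negligibly — a
predictive-only variant is available by flag. Confidence intervals are
jackknife: the model is refitted leaving out each of 7 stratified segments,
and the bound is the Student-t 95% interval on the jackknife standard
error. "Positive CI" in the screen means the lower bound exceeds zero.

**Q²** uses stratified K-fold cross-validation (default 7 folds, reduced
with a warning when the smallest class demands it):
Q² = 1 − PRESS/SS_tot, with PRESS accumulated over held-out
class-indicator residuals and SS_tot the total centered indicator sum of
squares — the textbook chemometrics convention. At the study's cohort size
(13 vs 16), the null distribution of Q² keeps roughly 10–20% of its mass
above zero: with n ≈ 29 a random labelling occasionally aligns with real
structure in X well enough to predict slightly better than the mean. This
is a sample-size property of the statistic, not estimator noise (repeated
CV averaging does not remove it); permutation experiments at this n should
expect ~80–95% of permutations at Q² ≤ 0, approaching ~95%+ only at double
the cohort.

## Differential screen

Pure conjunction per control-vs-dose comparison: VIP > 1.0 ∧ VIP CI lower
bound > 0 ∧ BH-adjusted two-sided Wilcoxon–Mann–Whitney p < 0.05. A
feature joins a tissue's differential set when it passes in **at least
one** dose comparison (the pooled-per-tissue reading of per-comparison
screens; an "all comparisons" mode is available). The Venn partition keys
on the annotation name when one is provided, so the same metabolite matches
across tissues; raw feature ids are the fallback.

## Sensitivity comparisons

**RF/ERT ensemble.** Per comparison: 2 ntree levels × 4 mtry fractions ×
125 repeats = 1000 records. Each repeat draws a stratified split with the
training share rounded *up* per class (the "two-thirds" of an odd class
size is ambiguous; ceiling is the documented choice), then trains a random
forest — bagged CART trees grown to purity, Gini splits, a fresh uniform
feature subset of size round(mtry·p) at every split (drawing past mtry only
until a valid split exists, the CART convention), majority vote with ties
to the first class — and records the test-set error. The forest is a
numba-compiled kernel so the 1000-model protocol runs in seconds on one
CPU; its error-rate distribution is cross-checked statistically against
scikit-learn's RandomForestClassifier in the tests. Tissue ERT
distributions are compared by two-sided Mann–Whitney U; the higher-ERT
tissue is the less sensitive one.

**Matched Q².** Control-vs-dose OPLS-DA models share one (n_pred, n_orth)
configuration — the study never states the counts it used, only that they
were matched, so they are explicit configuration here (default 1 + 1).

**MCFC.** Computed per treated sample against the control-group *median*
(mean by flag) of the same tissue: MCFC_i = Σⱼ max(x_ij/c_j, c_j/x_ij)
over the common metabolites. The aggregate is stated at group level in the
source method; the per-sample definition is this package's choice because
the rank test between tissues needs a per-sample distribution. MCFC ≥ m
with equality iff all fold changes are 1; it is invariant under inverting
every fold change and strictly increasing in any single |log FC|.

## Two-step CAST

Profiles are the per-metabolite (FC_L, FC_M, FC_H) triples vs control
(group means by default, medians by flag), correlated on the log₂ scale —
log₂ symmetrizes up- and down-regulation, matching the trend semantics of
the sub-cluster archetypes. Cortex and medulla rows for the same metabolite
stay distinct. Affinity is raw Pearson r (thresholds are quoted as
correlation coefficients); profiles with constant log-FC vectors cannot be
correlated and go to the unassigned pool.

CAST itself is the canonical add/remove scheme: open a cluster seeded by
the unassigned element with maximal total affinity over the remaining pool,
alternately add the outside element with the highest mean affinity to the
cluster (if ≥ t) and remove the member with the lowest (if < t), close when
stable. Mean affinity counts the element itself (diagonal 1), so singletons
are stable. All tie-breaks are by input order, making runs reproducible
without a seed; at termination every member's mean within-cluster affinity
is ≥ t, asserted directly and against a brute-force reimplementation on
small instances.

Step 1 runs at t₁ = 0.80; the **two largest** clusters are kept and signed
up/down by mean log₂ FC, all other profiles are excluded as poorly
dose-correlated (the source describes keeping two main clusters and
excluding the rest without giving the rule; "two largest" is the documented
interpretation). Step 2 re-clusters each kept cluster at t₂ = 0.98 and
labels each sub-cluster on its mean |log₂ FC| triple (a_L, a_M, a_H) with
threshold δ = 0.25: dose-monotone if both steps ≥ δ; step_M if the M-step
≥ δ and the H-step < δ in magnitude; step_H if the M-step < δ in magnitude
and the H-step ≥ δ; otherwise uncorrelated. The contributive set is the
medulla members of dose-monotone and step-M sub-clusters.

A geometric consequence of exact archetypes worth knowing: at t₁ = 0.80 a
single "up" cluster cannot stably hold step_M and step_H profiles together
(their pairwise r is 0.5), so one step family is typically excluded at
step 1 — the analogue of the excluded poorly-correlated metabolites in real
data, where continuously smeared profiles bridge the shapes. Archetype
recovery is therefore scored on the profiles *retained* by step 1: the
fraction of retained profiles whose sub-cluster label matches their planted
archetype. Under the recovery regime (|log₂ FC| = 1, noise CV 0.1) this
accuracy is ≥ 90% across seeds, with excluded profiles dominated by the
step family CAST cannot bridge plus the uncorrelated archetype, as
expected.

## Pipeline, problem sizes and runtime

`run_pipeline` sequences normalize → QC → screen → Venn → sensitivity
(ERT, Q², MCFC) → two-step CAST → heat-map data, writing tidy CSV/JSON
artifacts stamped with the config hash and seed; reruns with one config are
identical. Heat-map rows are autoscaled (constant rows flagged), clustered
with 1 − r distance and average linkage, leaf order deterministic.

Default experiment sizes keep the full suite and the acceptance script in
the minutes range on a single CPU: 100–300 features, the study's group
sizes, the full 1000-record ERT grid where the protocol's cardinality is
the point and reduced grids elsewhere. The sensitivity-direction
experiments use a weak-cortex (max |log₂ FC| 0.4) vs strong-medulla (1.5)
configuration at noise CV 0.2 with trend archetypes only, so that the
low-dose comparison is genuinely hard in cortex and easy in medulla — the
regime the tissue-comparison methods exist to resolve.

## What passing tests do and do not show

The generator produces clean log-normal intensities with known truth. It
does not simulate retention-time drift beyond constant jitter, batch
effects, missing values, censored low-intensity features, correlated
metabolite panels, or identification ambiguity. Passing recovery tests
therefore demonstrate that the pipeline's statistics behave as specified
under their own assumptions — not that any particular real dataset would
yield the same sets, counts or p-values.
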