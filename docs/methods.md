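# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `snpfs`, in the order the analysis chain uses them.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with ground truth retained for validation.

**Genotypes.** Each sample carries two haplotypes per SNP; dosage is their
sum, so hard-call dosages lie in {0, 1, 2} (the containers accept
fractional imputed dosages as well). LD is a haplotype-copy chain applied
to the latent uniform: within a block, a haplotype's uniform u_j is copied
from u_{j−1} with probability `ld_rho` and redrawn otherwise; the allele is
1 iff u_j < MAF_j. Copying the latent uniform rather than the allele keeps
every marginal MAF exact even when MAFs vary along a block, while giving
adjacent-SNP allele correlation ≈ `ld_rho` (dosage r² ≈ `ld_rho`² for
equal MAFs). Blocks restart every `ld_block_size` SNPs and never span a
chromosome boundary, so cross-block dosages are independent. Population
structure: each subpopulation perturbs every MAF by ±`subpop_maf_shift`
with a random sign per (SNP, subpopulation); the top principal components
of the standardized dosage matrix (truncated SVD) recover the
subpopulation labels, mimicking consortium-supplied genetic PCs.

Defaults, chosen once as plausible for a common-variant panel: MAF ~
U(0.05, 0.5), imputation info ~ U(0.92, 1.0), blocks of 10 SNPs at
`ld_rho` 0.3, one subpopulation (structure is opt-in), shift 0.05 when
structure is on. The generator does not attempt a realistic
allele-frequency spectrum, long-range LD, phasing, or X-chromosome
handling; passing tests show the analysis machinery behaves correctly
under its assumed structure, not that it would perform identically on real
biobank LD.

**Phenotype.** Each sample draws a latent subgroup from
`subgroup_fractions`; its case log-odds are
`baseline + Σ β·(dosage − mean dosage) + Σ γ·covariate` over that
subgroup's causal set. Centring the causal dosages keeps prevalence at
logistic(baseline) regardless of effect sizes. Disjoint causal sets across
subgroups encode genetic heterogeneity — different SNPs drive the trait in
different subjects. Subgroup labels are returned separately from the
cohort table and never enter the modelling stages. Covariates: age ~
N(57, 8), sex and array ~ Bernoulli(0.5), effects applied to standardized
covariates with defaults 0.1 (age), 0.2 (sex), 0 (array). The default
baseline log-odds in the planted-signal workflow is −0.4 (≈ 40% cases): a
case/control cohort has cases in the minority, and the down-sampling step
requires controls to outnumber cases.

**Bayes accuracy.** The Bayes classifier observes dosages (and optionally
covariates) but not the latent subgroup, so its per-sample case
probability marginalizes over subgroups with the prior fractions;
`bayes_accuracy` averages max(p, 1−p) over samples. This is the ceiling
any classifier can reach under the generative model and anchors the PRS
and search-engine comparisons. The planted-signal default (4 causal SNPs
private to one FS, β = 0.9 each at MAF ≈ 0.05–0.5) yields a Bayes accuracy
around 0.70 — deliberately stronger than a real GWAS signal so that
desk-scale run counts (tens, not thousands) can exhibit the recurrence
phenomenon.

**Annotations.** `simulate_annotations` lays out druggable genes, their
connected genes (200 kb spacing so extended intervals never collide), one
1 kb enhancer 40 kb downstream of each gene, and a per-SNP score table.
`pass_fraction` controls the probability that a SNP receives at least one
functionality score above threshold; passing SNPs draw one scorer above
its threshold uniformly, the rest below.

## Feature-set construction

Coordinates are BED-style 0-based half-open throughout; a SNP is the
single-base interval [pos, pos+1), so a SNP at an interval's end
coordinate is outside it. The promoter window is [TSS − 5 kb, TSS + 1 kb)
in strand-oriented coordinates (strand-agnostic mode treats every gene as
+); extended intervals clip at 0. A SNP in both body and enhancer is
labelled B (a single label per SNP is required; body containment is the
stronger statement). QC thresholds are strict inequalities
(MAF > 0.01, info > 0.9); functionality thresholds are inclusive
(CADD ≥ 10 ∨ GWAVA ≥ 0.5 ∨ TraP ≥ 0.459). A missing functionality score
fails its own condition; a SNP with all three missing is rejected rather
than silently dropped. The two filters commute, which the tests assert.

LD pruning is a greedy scan in genomic-position order: keep a SNP iff its
dosage r² with every already-kept SNP is ≤ the threshold (0.8 by default;
the threshold is a parameter, e.g. 0.6 for a GWAS-loci baseline panel).
The scan order is a parameter so alternative orderings can be compared;
zero-variance columns are treated as uncorrelated, retained, and logged.
Feature sets are named `druggable-connected` and hold the union of both
genes' retained SNPs ordered by genomic position, so any two FSs of a
druggable gene share all of that gene's SNPs.

## The search engine

A deliberately small evolutionary optimizer over pipeline specifications,
not a full AutoML system: the recurrence analysis depends on which FS wins
and how consistently, not on the breadth of the operator library.

- Template slots (e.g. FSS → transformer → classifier) are filled from
  operator grids: transformers {variance threshold, percentile selector,
  standardizer}, estimators {L2 logistic, random forest,
  histogram gradient boosting} (ridge and regressor counterparts for
  resAdj), each with a 2–4 point hyperparameter grid.
- Fitness is 5-fold CV on the training part (accuracy for classifiers, R²
  for regressors); fold assignment is fixed per run, and evaluations of an
  identical specification are memoized (deterministic evaluation, so the
  cache cannot change the winner).
- Tournament selection of size 2, one-slot resampling mutation, uniform
  slot-swap crossover (probability 0.5 each), single-individual elitism.
  The best-CV individual is returned; ties break by earliest creation.
  Everything is driven by one seeded generator, so a run is bit
  reproducible.
- Desk-scale workflow runs restrict the pool to the linear estimators
  (logistic / ridge) with the standardizer and variance-threshold
  transformers, and use population 10 × 10 generations: linear fits
  evaluate in milliseconds per fold, and FS-selection consistency does not
  hinge on tree ensembles being available. The full pool and larger
  budgets remain available through `OperatorPool` and `SearchBudget`.

Splits are 75/13/12 with floor-rounding for the two holdouts and the
remainder to train; the holdouts are disjoint by construction, so stage-1
model selection never sees the stage-2 evaluation data. The covariate
adjuster is an OLS fit per column on training rows only (pseudoinverse
with a logged warning when rank-deficient); applying it to any row set
subtracts the covariate prediction, and training residuals are orthogonal
to the covariates to numerical precision. Per-run failures (e.g. a
degenerate down-sampling) are recorded with their reason in the run result
rather than aborting the stage.

## Recurrence testing

The statistic is the maximum, over FSs, of the number of successful runs
selecting that FS; all argmax FSs are reported when tied. The null
permutes the phenotype over the full cohort *before* down-sampling (case
and control totals preserved, assignments scrambled; the identity
permutation is redrawn) and repeats the entire stage per permutation with
seeds derived from a documented counter scheme. Observed and null arms
must share a configuration digest; a mismatch aborts. The reported
p-value is the add-one empirical bound
p ≤ (1 + #{null ≥ observed}) / (1 + n_perm) — with few permutations this
is deliberately conservative and cannot certify small p-values.

Under permuted labels the engine's FS choice is not exactly uniform:
larger FSs give CV noise more room to overfit and are selected slightly
more often, so null maxima run a little above the symmetric-multinomial
prediction. The calibration test therefore stubs the selector to uniform
when checking the statistic's null law against the Monte-Carlo
multinomial maximum, and the planted-signal check compares the observed
count against the engine's *own* permutation null, which absorbs this
bias honestly.

## Explanation

**Kernel SHAP.** For one instance x and model output f, coalitions z
(subsets of the M features) are scored by imputing absent features from a
weighted background and averaging f; the attribution vector solves the
weighted least-squares system with kernel weight
(M−1)/(C(M,|z|)·|z|·(M−|z|)), with the local-accuracy constraint
base + Σφ = f(x) imposed by eliminating one unknown. With all 2^M − 2
non-trivial coalitions (used automatically for M ≤ 12) the solution equals
the exact Shapley value, which the tests verify against an independent
2^M-enumeration oracle at 1e−6. Sampled mode draws coalitions in
complement pairs with probability proportional to their kernel weight and
uses draw counts as regression weights; local accuracy still holds by
construction (1e−3 asserted), but attributions are estimates. The
background is k-means on the training rows with cluster-size weights and
each centroid coordinate snapped to the nearest observed value of that
feature, keeping dosage-like features on their support; the base value is
the weight-averaged model output over the centroids. For classifiers the
explained output is the predicted case probability.

**Cluster-number choice.** The Dunn index (single-linkage inter-cluster
distance over maximum cluster diameter, Euclidean; +∞ when every cluster
is a singleton) scores k-means clusterings across a k range; the highest
Dunn wins, ties to the smallest k, and the Dunn-vs-k table is always
produced for inspection. A `k_override` reproduces an analyst's manual
choice. The same machinery sizes the SHAP background (small default range
at desk scale) and clusters the well-predicted cases' SHAP vectors.

**Well-predicted cases.** Classification: true cases with predicted
probability ≥ 0.5. Regression: among true cases, the bottom quartile of
|observed − predicted| on the residualized scale, inclusive at the
boundary (ties can push the count above ⌈n/4⌉). Per-cluster rankings sort
features by mean |SHAP| descending with feature-id tie-breaks; the force
matrix exports (case, feature, shap, base, output) in long format with a
nearest-neighbour seriation order over SHAP rows so identical explanation
profiles sit adjacently.

**Permutation importance** shuffles one feature column at a time within
the evaluation set and reports the mean and spread of the score drop over
repeats; one shuffle permutation per repeat is shared across features, so
importances are exactly invariant to feature order.

## Orchestration, seeding, determinism

`AnalysisConfig` serializes to YAML and hashes via canonical JSON; every
artifact directory records it. All child seeds derive from
SeedSequence(base_seed, counter…) with documented counters per (stage,
run, permutation) — no global RNG state — and the full workflow is
byte-reproducible per (config, base_seed), which the tests assert. Every
search run appends to a JSON-lines ledger (config hash, seed, stage,
permutation index, outcome), and ledger counts reconcile with the
requested totals.

## Desk-scale problem sizes

The shipped defaults exercise the design at workstation scale: cohorts of
2,000 samples, 10 feature sets, 20 runs per stage, 5 permutations, and a
10 × 10 search budget, completing the whole chain in minutes on one CPU.
These sizes are the package's own test-scale choices; the stage machinery
itself has no scale assumptions, and all counts, budgets, and fractions
are configuration.

## Known limitations

- The recurrence statistic's null is empirical; no analytic theory or
  family-wise correction across multiple druggable genes is provided.
- Sampled-coalition SHAP has no error bound here beyond local accuracy;
  tolerances apply to this implementation's exact mode.
- The reduced operator pool cannot reproduce the pipeline diversity of a
  full AutoML search; conclusions about *which estimator* wins are out of
  scope (FS recurrence is the studied quantity).
- The generator's LD and effect-size defaults are plausible but not
  calibrated to any real trait or genotyping panel.
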