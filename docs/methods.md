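# Methods

## Scope and data model

The pipeline operates on two inputs: a **tissue compendium** (genes ×
libraries, one tissue label per library) used only for enrichment scoring,
and a **joint feature matrix** (genes + metabolites × samples, one
control/treatment label per sample).  Both are plain CSV; missing cells
(empty or `NA`) are legal only for metabolites, reflecting the
detection-floor censoring typical of LC-MS metabolomics.  Gene values may be
counts or normalized expression — every downstream stage sees only
log-transformed, per-feature standardized values, so the pipeline is
agnostic to the upstream quantification unit.

## Preprocessing

Order of operations: **impute → log → standardize.**

* Minimum-value imputation replaces each missing entry with the smallest
  observed value of its compound.  Imputing on the raw scale before the log
  guarantees positivity; the operation is idempotent.  All-missing rows are
  dropped with a logged warning rather than raised, so messy inputs flow.
* Welch's two-sample t-test (unequal variances, Welch–Satterthwaite df,
  two-sided p) is provided for per-feature condition screening on the logged
  values.  Features with zero variance in both groups get an undefined p and
  a warning.
* z-score standardization centers each feature to mean 0 and scales to
  sample (n−1) standard deviation 1; constant rows are dropped with a
  warning.  The n−1 denominator is used everywhere a standard deviation
  appears in the package.

## Enrichment

z = (x̄(tissue) − μ(background)) / σ(background), strict `>` at the
threshold (default 5).  The target tissue's libraries are excluded from the
background by default — including the signal being tested in its own
reference both shifts μ and inflates σ — but a flag restores the pooled
background.  Genes with σ(background) = 0 are reported with an undefined z
and `enriched = False` instead of being silently removed.  The score is
invariant to global rescaling of the compendium and monotone in the
threshold.

## k-means → random forest → hierarchical clustering

Standardized features are points in sample space.  k-means (Euclidean,
k-means++ seeding, 50 restarts, best inertia) gives a crude partition whose
purpose is *not* biological truth but load-balancing: it prevents one
dominant expression profile from crowding equally discriminative features
out of a single global ranking.  k defaults to 3 and is exposed, not
optimized — no silhouette/gap machinery.

Each cluster's features become the predictors of a random-forest classifier
of sample condition (bootstrap resampling, √p features per split, no depth
limit).  The default of 10,000 trees buys stable importance estimates at the
small sample sizes (~23) this design targets; importance is the
**un-normalized** mean decrease in Gini impurity — per-tree split-impurity
decreases summed and divided by the number of trees — because per-tree
normalization (as in scikit-learn's `feature_importances_`) would distort
comparisons across clusters of different sizes.  Out-of-bag accuracy is
reported per cluster as a sanity signal.  The top-29 panel size follows the
workflow convention; it is a plain configurable top-N, ties broken by
lexicographic feature id.

Prioritized panels are agglomeratively clustered (default Euclidean +
average linkage; correlation distance and single/complete/ward available).
Features are sorted by id before distance computation so the dendrogram is
invariant to input row order, with distance ties resolved identically on
every run.  Newick export assigns each branch the difference between its
parent's merge height and its own, making root-to-leaf paths equal the root
height (ultrametric rendering).

## Fork screening

The interaction model `A ~ 1 + r + g + r·g` (r = B/C, g = 0/1 condition) is
solved from the normal equations; the interaction coefficient equals the
treatment-minus-control slope difference, its SE uses the unbiased residual
variance and (X'X)⁻¹, and its p comes from the t distribution with n − 4 df.
Choices:

* Ratios are taken on post-imputation, **raw** (pre-log) abundances,
  following the metabolite-ratio association lineage; a log-scale variant is
  a caller-side transform.
* Ordered triplets are kept distinct — (A, B, C) and (A, C, B) probe
  different geometries — and enumeration is deduplicated and sorted.
* Significance uses the raw p < α rule (α default 0.05) to match the
  workflow convention; BH-adjusted p-values are always attached because
  triplet screens are many-test.
* Degenerate cases never abort a screen: denominators at or below 1e-12 flag
  `degenerate-denominator`, rank-deficient designs flag `collinear`, and
  exact fits (residual variance ≤ 1e-24 relative) flag `saturated` with an
  undefined p while still reporting the slopes.
* Fork screening runs on the full metabolome sample set, not the
  transcriptome intersection, since only metabolites enter the model.
* When no role lists are configured, candidates default to the prioritized
  metabolites, capped at the 10 best-ranked (`max_fork_candidates`): cubing
  a full 3 × 29 panel yields tens of thousands of triplets with no gain in
  interpretability.

## Pipeline

Stages (enrich → join → preprocess → k-means → rank → dendrogram → forks)
are pure functions of config + seed + inputs; per-stage random seeds are
derived deterministically (forest seed = run seed + cluster index), every
artifact is delimited text or JSON, and two runs with the same config are
byte-identical.  Sample reconciliation between the gene and metabolite
layers defaults to the intersection (joint feature vectors need complete
columns); a union mode carries missing gene values instead.  Failures abort
with the stage name while retaining partial outputs.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, with
defaults mirroring the study design it models: 16 target-tissue + 50
background libraries behind the enrichment step, a 12 control + 11 treatment
cohort, 20 genes enriched at 8 σ, 3 latent profile groups, 10 discriminative
features at 3 σ, 5 % missingness.

* **Compendium:** per-gene Gaussian background (mean ~N(8, 2), sd
  ~U(0.5, 1.5)); enriched genes have their target-tissue mean raised by
  `enrichment_effect × sd`.
* **Cohort:** each non-fork feature follows a unit-variance latent profile
  `x = (sep·f_group + ε)/√(1+sep²) + shift·[discriminative]·[treated]`, so
  `profile_separation` sets the within-group correlation sep²/(1+sep²) and
  `discriminative_shift` is in total-sd units.  Genes are emitted as rounded
  log-normal counts `exp(N(6, .5) + 0.5x)` — heavy-tailed positivity is all
  downstream stages need, since they standardize; metabolites as log-normal
  abundances `exp(N(2, .5) + 0.7x)`, strictly positive before censoring.
* **Forks** occupy dedicated metabolite ids outside the group structure
  (group-correlated B and C would make the ratio nearly constant and the
  design collinear): B, C ~ exp(N(1, 0.3)) and
  `A = 8·noise_sd + slope(condition)·B/C + N(0, noise_sd)`, floored at 1e-9.
  The intercept keeps A positive and is absorbed by the model.
* **Missingness** is low-abundance censoring — entries in the bottom
  quartile of their compound go missing with probability min(1,
  4·missing_rate), i.e. an overall rate ≈ `missing_rate`.  The real
  mechanism in LC-MS panels is not observable from the data; censoring at
  low abundance is the assumption that motivates minimum-value imputation.
* Seeding uses one root seed with named substreams per stage
  (compendium/cohort/missingness), so regenerating one output never perturbs
  another.

What the generator does **not** emulate: library-size variation and
count-specific mean–variance coupling, batch structure, correlated
missingness across compounds, or any attempt to match a real dataset's
moments.  Passing recovery tests therefore demonstrates correctness of the
algorithms under their stated assumptions, not performance on real tissue
panels.

## Verification problem sizes

Recovery and calibration checks run at: enrichment 200 genes × 66 libraries
over 20 seeds; k-means 300 features × 23 samples at 10 σ separation over 20
seeds; forest prioritization 300 features over 50 seeds at 500 trees (a size
at which rankings for n = 23 samples are already stable; the pipeline default
stays 10,000); fork type-I error on 2,000 equal-slope replicates; fork power
on 100 seeds of one slope-difference-3 fork against 12 equal-slope forks.
The equal-slope-fork null is used (rather than unstructured log-normal
metabolites) because OLS t-tests on heavy-tailed raw abundances are
leverage-anticonservative — those triplets are interesting screen output,
but they are not calibration nulls.

## Known limitations

* Gini importance is biased toward features with more split points; no
  permutation-importance variant is provided.
* The raw-p fork rule is anticonservative under many-test screens and
  heavy-tailed abundances; treat `adjusted_p` as the inferential column.
* k is fixed, not selected; dendrogram topology claims should be treated as
  qualitative (no bootstrap support).
* The Welch screen assumes approximate log-normality; zero-inflated
  compounds violate it.
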