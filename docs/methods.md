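# Methods

`microtnt` implements a random-forest workflow for deciding whether a
contaminant — 2,4,6-trinitrotoluene (TNT) in marine sediments — is present,
using the sediment's 16S rRNA amplicon community profile and geochemical
covariates as predictors. This note documents the statistical model behind
each stage, the defaults and why they were chosen, the numerical decisions,
and the limitations a user should know about.

## Problem setting and assumptions

The central premise is that a chronic environmental influence leaves a
*microbial fingerprint*: a subset of taxa whose joint abundances shift under
the influence even when that influence is not a main driver of community
composition. The workflow therefore has to (1) classify a weak signal
against a dominant confounding gradient (grain size), (2) identify the
fingerprint taxa with error control, and (3) characterise which samples the
classifier cannot decide, because those carry information of their own
(e.g., historically contaminated sediments whose TNT has dissipated).

Assumptions: samples are exchangeable once contextual subsets are thinned
(see curation); the response is binary (concentration above/below the
detection limit); community features enter as relative abundances without
further transformation — random forests are invariant to monotone
per-feature rescaling, so compositional log-ratio transforms are not
required for classification (they would matter for linear models).

## Curation

Field campaigns produce clustered designs: several samples from the same
cruise, experiment and area, metres apart. If such a subset carries only
one response class, a classifier can learn the subset identity instead of
the contamination signal. The exclusion guideline flags a subset when all
of: same cruise, same experiment, same area, all pairwise haversine
distances below `distance_threshold_m` (default 20 m, WGS84 sphere,
R = 6371 km — sub-metre datum effects are irrelevant at this scale), and
either a single response class or a minority class of at most
`imbalance_rule` (default 1) samples. All but `retain_per_subset`
(default 1) members are removed, keeping the lowest sample id so the result
is deterministic. The guideline is idempotent.

Technical replicate libraries are averaged *after* conversion to relative
abundance, so unequal sequencing depths do not weight the mean.

The response is binarized at the TNT detection limit of 0.044 pmol·g⁻¹ wet
sediment (0.01 ng·g⁻¹ at M = 227.13 g·mol⁻¹); a concentration exactly at
the limit counts as detected ("present").

## Feature engineering

Relative abundances (%) are computed per library. A feature survives the
abundance filter iff it exceeds the threshold in at least one sample
(strict comparison; survivors are left unchanged, so row sums may drop
below 100). The threshold grid is
{0.02, 0.04, 0.06, 0.08, 0.1, 0.2, 0.4, 0.6, 0.8, 1}%.

Order matters and is fixed: thresholding happens at ASV rank first, and
only surviving ASVs are agglomerated to genus…phylum by summing within
identical lineage prefixes. ASVs lacking a label at the target rank are
pooled as "unclassified *deepest annotated parent*". Grouping keys are full
lineage prefixes, so identically named taxa under different parents stay
distinct.

For the neural-network path only, numeric columns are z-scored with the
population (divide-by-n) standard deviation — the choice is recorded in the
matrix's scaling state so it is auditable — and declared categoricals are
one-hot encoded. Constant columns are left at 0 with a warning rather than
producing NaNs.

## Forest layer

Forests are scikit-learn classification forests: Gini criterion, fully
grown trees (minimum node size 1), bootstrap sampling. The number of
candidate variables per split follows the *mtry factor* convention:
`mtry = min(floor(sqrt(p)) × factor, p)`. With 542 features and factor 5
this gives 115.

Out-of-bag (OOB) predictions are assembled from each tree's predictions on
the samples outside its bootstrap; vote ties are broken toward the class
with larger training prevalence, then lexicographically — deterministic and
documented. Samples never OOB (possible at very small tree counts) are
flagged "undefined" and excluded from the OOB error with a warning.

The proximity of two samples is the fraction of trees in which they share a
terminal node. Unsupervised classification appends a synthetic copy of the
data with every column independently permuted (breaking all
between-variable structure) and trains a forest to separate real from
synthetic rows; the proximity of the real rows then reflects the intrinsic
correlation structure.

**Caveat (measured):** on tie-free continuous data the OOB error of that
real-vs-synthetic forest is not a usable "is there structure?" statistic.
Every value of a permuted column exists in exactly one real and one
synthetic row, so a fully grown tree purifies leaves around exact values
and each OOB sample lands with its opposite-class value partners: OOB
accuracy falls *below* chance (we measured 0.01–0.14 on i.i.d. noise)
without indicating any real structure. The artifact can only depress
accuracy, never fake structure, and is diluted on sparse, tie-rich
abundance tables; conclusions should rest on the proximity matrix, which is
what the downstream ordination uses.

## Variable importance with p-values

Two schemes are provided, matching the two ways the workflow ranks
variables.

**Oriented holdout importance with mirrored-null p-values**
(`importance_corrected_janitza`). A signed, corrected-impurity-style score:
samples are split once into two stratified halves; a forest grown on one
half has every split re-scored on the other half. A split on feature *j*
earns `orientation × N_l·N_r/N × (p̂₁(left) − p̂₁(right))`, where the
orientation (which child is enriched for which class) was fitted on the
training half and the enrichment difference is computed from the evaluation
half; both directions (A→B and B→A) are averaged, and the score is averaged
over `m` such model pairs. Design points that matter, each validated
empirically on pure-noise data (150 × 500):

- *Orientation is essential.* An unsigned holdout Gini decrease is
  non-negative for any partition, and even after subtracting its exact
  hypergeometric chance expectation `N·G/(N−1)` it remains chi-square-
  skewed, because Gini rewards |structure| in the evaluation half
  regardless of direction. The oriented statistic is a product of a
  training-half sign and an evaluation-half difference that are independent
  under the null, hence symmetric around zero.
- *The half-partition is fixed across the m models.* With fresh partitions
  per model the two halves' chance associations are coupled (their product
  averages to L² − e² across partitions), which skews the averaged score;
  with a fixed partition the average stays symmetric. Measured: fraction of
  positive null scores 0.27 (fresh) vs 0.49 (fixed).
- Splits whose evaluation-half samples all route to one child carry no
  information about the split and contribute zero.

p-values use the mirrored empirical null built from all non-positive
averaged scores, M = {−s : s ≤ 0} ∪ {s : s ≤ 0}, with
p = (#{M ≥ s} + 1)/(|M| + 1); the construction requires a symmetric null,
which is why the points above matter. Measured calibration at the defaults
(20 models × 500 trees, mtry factor 5, three independent noise datasets):
type-I error 0.046–0.062 at the 0.05 level, Kolmogorov–Smirnov distance
from uniform 0.023–0.074. A run in which every score is positive (tiny
feature sets with universally strong signal) cannot form the null and
raises with advice to add features or models.

**Permutation importance with response-permutation p-values**
(`importance_permutation_altmann`). The observed score is Breiman-style OOB
permutation importance (mean accuracy drop over trees when one feature is
permuted within the OOB samples). The per-feature null is built by
re-training on response-permuted data `n_perm` times;
p = (r + 1)/(n_perm + 1), so the smallest attainable p is 1/(n_perm + 1).
This scheme is exactly calibrated by construction but costs `n_perm`
forest trainings; it is the default for the small environmental-variable
block, while the holdout scheme serves the large community block.

Importance scores are on the package's own scale (class-proportion units
per evaluation sample); selection cutoffs must be chosen on that scale.
`select_top_features` applies strict `importance > cutoff` and
`p < p_cutoff` and returns features ordered by descending importance.

## Evaluation protocol

`make_splits` draws k unstratified pseudo-random splits; the training size
is the round-half-down of n × 0.75, so 150 samples give 112/38 — matching
the printed sizes of the study design this emulates. Unstratified sampling
is deliberate: holdout class ratios should drift as they do in practice.

The score is balanced accuracy, (sensitivity + specificity)/2, which is
invariant to class swaps and robust to imbalance. Grid-search validation
scores are OOB estimates on the training partition only; a
`GuardedResponse` wrapper raises `LeakageError` if any holdout label is
touched before `evaluate_holdout` unlocks it, and a test drives a canary
through that guard. Cross-split averaging of validation scores for
hyperparameter choice reuses the same splits repeatedly — an acknowledged
mild information leak across splits, inherent to the design; the holdout
estimate is the honest figure.

Input sets (community / sediment / combined; Full / Top / Non-Top) are
compared by Welch's unequal-variance one-way ANOVA followed by Tukey HSD at
95% family-wise confidence, flagged at adjusted p < 0.005.

## Ordination and environmental correlation

The proximity matrix is a similarity; "PCA on the proximity matrix" is
realized as classical principal-coordinates analysis (PCoA, Gower
double-centering) of D = 1 − P, with a square-root correction of D when
negative eigenvalues arise. Explained fractions are eigenvalues over the
positive-eigenvalue sum. Ordinations are rotation/sign-indeterminate; the
package fixes signs so the lexicographically smallest sample id scores
non-negatively, and tests compare inter-point distances rather than raw
coordinates.

Environmental vectors are fitted by least squares onto the first two axes;
R² is the squared multiple correlation and its p-value the permutation tail
probability over row permutations of the variable (vectorized; default
9,999 permutations). The implementation is cross-checked against vegan's
`envfit` in the test suite. The display rule p < 0.001 and R² > 0.3 is
available as a filter. Spearman rank correlations between sediment
variables are ordered by average-linkage clustering on 1 − |rho| and
flagged at p < 0.01; zero-variance columns yield NaN and are placed at unit
distance.

## Robustness and resilience

`consistency_analysis` trains many independently seeded forests on *all*
samples and reads each model's per-sample OOB prediction — the only
leak-free per-sample error rate when training uses every sample. Rates are
percentages over models; rates below 0.5% or above 99.5% are rounded to
0/100 ("robustly" classified), rates in between are left untouched.

`false_positive_resilience` partitions the consistently-absent samples with
nonzero false-positive rates by metabolite presence (any
amino-/diamino-nitrotoluene above zero) and reports counts, mean and range
per partition plus the Spearman correlation of rate with summed metabolite
concentration. The scientific mechanism: a sediment contaminated long
enough ago that TNT has dissipated retains both its metabolites and its
fingerprint-shaped community, so it *should* be predicted "present" — the
false positive is the signal.

The ANN validator is a small feed-forward network (hidden layers 50 and 40,
ReLU; sigmoid output; binary cross-entropy; Adam; mini-batches of 4; at
most 100 epochs; no regularization) under 333× repeated, unstratified
3-fold cross-validation — 999 model fits, each sample validated once per
repeat. Early stopping is realized as loss-plateau patience (2 epochs),
because a validation-score rule fires before mini-batch training on ~100
samples has left its cold start (measured: chance-level accuracy with the
score rule vs convergence with the loss rule). Weight initialization is the
backend's seeded Glorot-uniform scheme. `cross_algorithm_agreement`
tabulates forest-wrong/right × ANN-wrong/right with sample lists, calling a
sample wrong when its rate exceeds 50%.

## Synthetic data

The generator draws, per sample: a latent grain-size gradient g ~ U(0,1);
binary TNT status at 45% prevalence (fixed count, shuffled); "historical"
flags for 10% of the TNT-absent samples. Per taxon: a baseline
log-abundance N(0, 2); with probability 0.6 a gradient slope N(0, 1.5); the
25 indicator taxa instead draw baselines from N(0.5, 0.75) — the detectable
mid-range, as real fingerprint taxa peak around 0.1–5% relative abundance —
and receive +log(2) when TNT is present *or* the sample is historical.
Cell-level noise N(0, 0.5) is added, rows are closed to probabilities
(softmax) and counts drawn multinomially at log-normal depth around 80,000
reads (the realistic mean library size). Environmental covariates comprise
four grain-size fractions closed to 100% and driven monotonically by g,
~18 further gradient-correlated variables, and independent noise variables,
41 in total. TNT concentrations for present samples are log-normal above
the detection limit; metabolites are positive with probability 0.9 for
present samples and guaranteed (at least one) for historical samples.
Synthetic lineages nest 8 phyla down to ~p/3 genera with 10% of ASVs
missing a genus label, so agglomeration and "unclassified parent" labelling
are exercised.

What the generator does *not* emulate: phylogenetic signal, spatial
autocorrelation, PCR/sequencing error, overdispersion beyond depth
variation, and taxon-taxon interaction structure. Passing tests therefore
demonstrate the pipeline's contracts and statistical calibration, not
performance on real sediment data.

## Problem sizes used in the test suite

The suite scales simulations to what the contracts need: importance
calibration runs at 150 × 500 features with 20 models of 500 trees;
fingerprint recovery at the full generator defaults (150 × 600) with
500-tree forests over 5 seeds; consistency at 200 models of 100 trees;
envfit calibration at 200 repeats × 999 permutations. Tree counts are the
main cost dial and do not change any of the tested properties once in the
hundreds; the study-scale 10,000-tree, 1,000-model settings remain the
documented defaults of the corresponding operations.

## Known limitations

- The holdout importance score depends on one random half-partition per
  run; feature ranks for borderline features vary more between seeds than
  ranger-style in-bag scores. Averaging more models narrows forest noise
  but not partition choice; this is the price of the calibrated null.
- The mirrored-null p-value is a heuristic outside the global null
  (correlated features with a few strong signals shift the non-positive
  pool); the permutation scheme is the fallback when exactness matters.
- BIOM support covers dense community matrices in the 2.1 HDF5 and classic
  JSON dialects, not rich observation/sample metadata.
- The exclusion guideline treats missing coordinates by excluding the
  sample from the distance check (with a warning), not by imputation.
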