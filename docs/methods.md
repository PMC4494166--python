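# Methods

This note documents the models and procedures implemented in `dxrank`, the
defaults chosen where the methodology left the design open, and what the
synthetic study conditions do and do not establish.

## Cohort model and coding

Each subject carries a dataset id (1–5), age in years, gender (1 male /
2 female — a package convention; the coding of gender was not fixed by the
source studies), a cystoscopy truth label, and up to four coded test results.
Cytology is four-level (1 negative, 2 atypical, 3 suspicious, 4 positive; 1–2
map to binary-negative, 3–4 to binary-positive); NMP22, FISH and Cxbladder
Detect are binary (1 negative, 2 positive).  Every test cell has a provenance
flag (measured / imputed / missing) serialized in `*_src` sidecar CSV
columns; missing cells serialize as empty fields.  "Other-cause" diagnoses
are kept as a distinct truth value at load time so the reclassification rule
is observable, and reclassified to non-UC during integration.

## Synthetic study design

`canonical_design()` encodes the five-dataset blueprint: 476 (63 UC / 411
non-UC, cytology+NMP22+Cxbladder), 94 (6/74, cytology+Cxbladder), 84 (5/63,
cytology+Cxbladder), 200 (6/187, cytology+NMP22+FISH) and 124 (9/115, all
four tests with 2 NMP22 and 3 cytology cells individually missing).  The gap
between original and analyzed counts becomes invalid records, split evenly
between no-truth records (all of the dataset's tests measured) and
single-test records (odd remainders go to no-truth); the split is not
documented in the source material and is configurable.

The generator draws each subject's binary test outcomes conditionally
independent given the truth, with P(positive | UC) = sensitivity and
P(positive | non-UC) = 1 − specificity.  Defaults are the measured accuracies
of the integrated case-study data: cytology 45.5/96.3, NMP22 44.9/89.0, FISH
40.0/87.3, Cxbladder Detect 79.5/82.2 (%).  A Gaussian-copula correlation
knob (shared latent severity loading, default 0) exists because no joint
distribution is documented; enabling it changes the joint law but not the
margins.  Cytology's four-level code splits binary calls with 40 % atypical
among negatives and 50 % suspicious among positives (conventions,
configurable).  Age is truncated normal (mean 65, sd 12, floor 18) and 70 %
of subjects are male — plausible urology-clinic defaults, not sourced.
Other-cause diagnoses are 10 % of analyzed non-UC records.

Two deliberate generator properties:

* The five individually missing cells in Dataset 5 are blanked in five
  *distinct* records.  This guarantees that the documented seven-step plan is
  always feasible (a record missing both NMP22 and cytology would have no
  complete input row in step 1).
* Single-test invalid records carry a real truth label drawn at the dataset's
  prevalence; no-truth records have all tests generated from a latent truth.

What the generator does *not* emulate: between-test correlation beyond the
optional copula, site- or assay-level effects, age/gender association with
disease, and any subject-level structure of the real cohorts.  Passing tests
therefore demonstrate that the machinery recovers its inputs under the design
structure, not that the original numerical tables are reproduced.

### A documented count discrepancy

The published imputation table lists 80 NMP22 values imputed in Dataset 3,
although that dataset's analyzed size implies only 68; the accompanying text
total (NMP22 missing for 162 patients) matches 2+80+80, not the dataset
sizes.  The canonical design follows the dataset sizes (68 for Dataset 3,
NMP22 missing total 150) and the plan's merged NMP22 step carries no expected
count rather than silently patching the table.

## Integration

Discard precedence is fixed: unknown-truth first, then fewer than two
non-missing tests (age and gender never count toward the threshold), so audit
reasons are unambiguous; surviving other-cause records are reclassified to
non-UC.  Integration is idempotent and conserves counts per dataset and
overall.  Empty input, or input whose every record is discarded, raises with
the audit attached.

## SNR ranking

The separation index is |μ_UC − μ_non-UC| / (σ_UC + σ_non-UC) with
*population* (ddof 0) standard deviations, computed per variable on complete
cases for that variable.  Multilevel coding (cytology on 1–4) is the default;
a binary coding is available for sensitivity analysis (the index is invariant
to affine recoding, so binary tests are unaffected).  Ties in the descending
ordering break alphabetically.  Degenerate inputs: equal constant groups give
0; a variable constant in each group with different means has unbounded
separation — `snr_index` raises on it, while `rank_tests` reports it as
+inf and ranks it first; a variable empty in one group is reported with an
undefined index and excluded from the ordering.

The exact functional form used for the published index values is not
recoverable (it lived in supplementary material), so the printed values
(0.48 / 0.30 / 0.21 / 0.19) are not reproduction targets; only the ranking
behaviour is.

## Empirical accuracy

Sensitivity and specificity are plain proportions; the 95 % CI is the Wald
interval of an intercept-only logistic model per truth group,
expit(logit(p̂) ± z·sqrt(1/k + 1/(n−k))) — with a binary outcome and no
covariates, univariate logistic regression reduces to exactly this.  Boundary
proportions (k = 0 or k = n) get a 0.5 continuity correction for the interval
only, and the interval is clamped to contain the point estimate.  Percentages
are reported to one decimal.

## Step-wise imputation

The canonical plan ships as data (its idiosyncratic ordering cannot be
derived from "smallest block first" alone); `auto_plan` is a separate greedy
heuristic that picks, among feasible (dataset, test) blocks, the one with the
fewest missing cells (ties by test name then dataset id), re-evaluating after
each step and raising on deadlock.  Training pools require a *measured*
target and non-missing inputs; imputed values of input variables from earlier
steps are used when a step requires them.  Supervised mode appends the truth
(coded non-UC 1 / UC 2) to every step's inputs.  Measured cells are never
modified; the "at least 70 % known data per training pool" property is logged
per step and violations warn rather than abort, since it describes the
process rather than gating it.

Backend details (the source supplements are unavailable; these are package
defaults, all configurable):

* **kNN** — Euclidean distance on training-pool-standardized inputs (codes
  treated numerically; zero-variance columns scale 1).  Prediction is the
  majority code among the k nearest; ties break by smallest summed distance,
  then lowest code; equal distances resolve by training-row order.
* **MLR** — least-squares linear regression of the numeric code on the
  inputs (closed form), predictions rounded to the nearest code and clamped
  to the alphabet.  A singular design matrix raises, naming the collinear
  inputs.  The wording of the source is followed (linear, not logistic); a
  multinomial-logistic variant is available behind `BackendConfig(logistic=True)`.
* **MLP** — scikit-learn `MLPClassifier` with one hidden layer of 8 logistic
  units, 500 epochs, seeded initialisation; inputs standardized; predicts the
  argmax code.  A constant training target short-circuits to that constant
  for both global backends.

Cytology is imputed on its four-level alphabet; as an input it contributes
its 1–4 code.

## Imputation validation

Leave-one-out accuracy holds out each complete record of a training pool,
imputes its target from the remainder, and scores agreement on the binary
diagnostic mapping (a strict-code option exists for cytology).  The pool for
a test is the training pool of the plan's *final* step targeting it — the
largest documented pool; whether the original validation pooled per dataset
or globally is unstated.  For the costly model backends an optional seeded
subsample of held-out rows (`max_eval`) bounds the evaluation while each
held-out row still trains on the full remainder.

Distortion is reported as measured-minus-imputed differences of sensitivity
and specificity in percentage points, with the average absolute difference
(|Δsens| + |Δspec|)/2.  The "best" method under the combined objective is
lexicographic: highest mean LOO accuracy, then lowest mean average absolute
difference (no weighting between the two criteria is documented).

## Bayesian accuracy

Per truth group, the joint binary outcome of the four tests is multinomial
over 16 cells with a flat Dirichlet(1,…,1) prior — the standard
simplex-consistent reading of "uniform (0,1) priors for each probability".
The chain alternates data augmentation (each incomplete subject's cell drawn
from the current group probabilities restricted and renormalized over the
cells compatible with its observed outcomes) with conjugate Dirichlet draws
given the augmented counts; subjects sharing a partial outcome are aggregated
so each iteration draws one multinomial per unique pattern.  Defaults: 2000
iterations, burn-in 500 (the original burn-in is unspecified), single chain.
Cytology enters on its binary mapping.  Sensitivity of a test is the sum of
the Tumor group's 8 test-positive cell probabilities per draw; point
estimates are posterior means and CIs the 2.5/97.5 percentiles.  With
complete data the posterior cell mean is (count+1)/(n+16), which serves as
the oracle in tests.  All-tests-missing subjects cannot occur after
integration but the sampler handles them (16 compatible cells).

## Pipeline report and scatter surrogate

The comparison report collects SNR, sensitivity and specificity (with CIs and
per-criterion ranks) per test under the measured condition and each
backend × mode imputed condition.  Instead of rendering contour plots, the
scatter table projects each condition onto the sensitivity/specificity plane
and reports the Euclidean distance from Cxbladder Detect's point to the
centroid of the other three tests — a machine-checkable separation statistic
(0 when all tests coincide).

## Problem sizes and test scale

All structural checks run on the canonical 978-record design (seconds).
Stochastic recovery checks average 200 replicate cohorts; qualitative-ranking
checks use 10 replicate cohorts across all five backends and both modes;
Gibbs oracle checks use 4000 iterations on ~50-record toys.  These sizes were
chosen to give comfortable statistical resolution at desk scale.

## Known limitations and observed behaviour

* Under the default study conditions, supervised *model-based* imputation of
  the heavily missing FISH block is knife-edge: the round-to-code threshold
  of MLR (and the MLP decision boundary) sits near the fitted UC-group
  prediction, so a minority of replicate cohorts (roughly one in six)
  produce imputed FISH values that act as a near-perfect truth proxy and
  out-rank Cxbladder Detect on SNR.  The qualitative-ranking check is
  therefore a strict-majority expectation over replicates, not a per-seed
  certainty.  kNN backends and all unsupervised conditions are stable.
* The logit-Wald interval is one of several defensible CI choices
  (Wilson/score and exact intervals differ at small n); the package fixes
  the logistic-regression-Wald form.
* Single-value imputation only; no multiple imputation with pooling, no
  class resampling, no k-fold validation variants, no record linkage across
  datasets, and no figure rendering.
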