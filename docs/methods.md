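# Methods

## The analysis pipeline

`memcult` analyses two-group old/new recognition experiments.  Each
participant first sees 150 images and rates, on a 6-point scale, whether
they expect to remember each one (encoding phase), then judges 300 images
(the 150 seen plus 150 unseen) on the same 6-point scale for "did you see
this?" (recognition phase).  Raw responses follow the questionnaire
convention 1 = definitely yes … 6 = definitely no and are reverse-coded
exactly once, at scoring time (r → 7 − r), so higher values always mean
more confidence the item was seen; the scored table records this in its
metadata to prevent double reversal.

**Memorability** of stimulus s within group g is

    m(s, g) = mean reverse-coded response when s was old
            − mean reverse-coded response when s was new,

a mean-difference score in [−5, 5] that rises with hits and falls with
false alarms.  No signal-detection modelling (d′, ROC) is attempted; the
mean-difference score is the quantity of interest throughout.  Prediction
scores (mean reverse-coded encoding response) are computed and reported
but deliberately excluded from downstream modelling: encoding-phase
predictions are known to be weakly diagnostic, and keeping them out of the
models keeps the dependent variable purely behavioural recognition.

**Consistency and quadrants.**  Cross-group agreement is the Pearson
correlation of the two groups' scores over common stimuli.  A stimulus is
"memorable" within a group iff its score *strictly exceeds* the group
median (`strict_gt`); the 2×2 of the two indicators yields quadrants
1 (both) / 2 (group A only) / 3 (neither) / 4 (group B only).  The strict
policy is one of two defensible tie conventions and is configurable
(`ge`); the choice is recorded in every output.  Dimension scores of
quadrant-2 versus quadrant-4 stimuli are compared per dimension with
Welch's unequal-variance t test, one-tailed.  When no direction is given,
the tested direction is taken from the observed sign of the mean
difference and the row is flagged `post_hoc_direction` — such p values are
not calibrated and the flag makes that auditable.  No multiple-testing
correction is applied by default (raw one-tailed p values are the
reporting convention here); Benjamini–Hochberg is available as an option.

**Dimension transfer.**  One elastic-net regression per object dimension
maps a stimulus-embedding matrix to that dimension's reference scores.
Hyperparameters (mixing parameter ∈ {0.1, 0.5, 0.9}, penalty strength
log-spaced 10⁻⁴…10¹, 7 points) are chosen per dimension by 10-fold
cross-validation maximizing the *mean validation Pearson r* — the metric
in which transfer quality is reported — rather than MSE.  Embeddings are
standardized per feature with training-fold statistics only, so no
information leaks from validation folds.  Both cross-validated and
training-set correlations are reported, since the two can differ
materially.  A zero penalty is honoured exactly by switching to ordinary
least squares.  Extracting embeddings from images or networks is out of
scope; any numeric embedding matrix is accepted.

**SVM-RFE.**  Classification of group-A-only vs group-B-only memorable
stimuli uses a linear hinge-loss SVM (min ½‖w‖² + C Σξ; C defaults to 1)
inside recursive feature elimination.  Per step: 6 repeats of stratified
10-fold CV; validation accuracies averaged into one trace entry; |w_j|
averaged over all 60 fold models; the dimension with the smallest average
|w_j| eliminated (ties broken to the lexicographically smallest name).
Features are z-scored per dimension from training-fold statistics — weight
magnitudes are only comparable across dimensions on a common scale, and a
constant feature then scales to zero weight and exits first.  The linear
kernel is required: per-dimension elimination by weights is only
well-defined for a linear decision function.  Absolute values are averaged
(not signed weights, which can cancel).  Fold assignment is drawn once per
repeat from the run seed and reused at every step, making the procedure
deterministic and equivariant under feature permutation.  The accuracy
trace is smoothed with a centered 7-point moving average whose window
truncates at the edges; the dimensions surviving at the smoothed maximum
are selected, ties going to the earlier step (larger subset).

A caveat worth stating: because elimination decisions use weight
information from models trained on essentially the whole sample, the CV
accuracies at later steps are optimistically biased — under label
permutation the trace starts at chance but drifts to ≈0.59 by the late
steps (d = 20, n = 143).  This is a property of eliminate-outside-the-CV
RFE itself, not of this implementation (an independent brute-force
reimplementation reproduces the traces exactly).  The *first* trace entry
is an unbiased accuracy estimate; the peak location is still informative
for subset selection, but the peak accuracy value should not be read as an
unbiased performance estimate.

**Culture-specific models.**  Group A's culture-specific memorability is
the residual of OLS-regressing A's scores on B's (and vice versa): the
shared component is whatever one group's scores can linearly predict of
the other's.  Dimensions are categorized by their labels as life, nonlife
or mixed; mixed dimensions never enter any model.  For each category the
k = 6 dimensions with the largest |Pearson r| against the *residual*
scores (the model's dependent variable; correlation against raw scores is
available via `selection_target="raw"`) become predictors of a multiple
OLS regression reported as R², overall F with its p value, and the
residual standard error √(SSR/(n−k−1)).  Selection and fitting use the
same data, mirroring the standard exploratory practice; the resulting
optimism is real and a split-sample analysis can be composed from the
primitives if unbiased R² is needed.  Absolute (not signed) correlation is
used for selection, with ties broken by dimension name.

## The synthetic generator

The generator emulates the study design so that every stage has a ground
truth: 120 participants per group, 600 stimuli randomly split into 4
subsets of 150, participants spread evenly over the 12 ordered (old, new)
subset pairs so each subset is old for exactly 30 and new for exactly 30
participants of each group.

Responses come from a latent-Gaussian cumulative-link model.  Latent
memorability of stimulus s in group g:

    m(g, s) = x_s·w_shared + u_s  +  x_s·w_g + v(g, s)

with x_s the column-centered dimension scores, u ~ N(0, σ²_shared) shared
across groups, v ~ N(0, σ²_group) independent per group.  An old-item
recognition response is the ordinal cut (five strictly increasing
thresholds) of m + old_offset + ε, ε ~ N(0, σ²_trial); a new-item response
cuts new_item_leak·m + new_offset + ε.  The latent drives old items fully
and new items only through the familiarity leak (default 0): a stimulus
effect entering both statuses equally would cancel out of the old-minus-new
difference score, leaving no recoverable ground truth — the leak parameter
makes that attenuation explorable.  Encoding predictions cut an attenuated
latent (factor 0.5) — predictions correlate with, but undersell, actual
memorability.  Dimension scores are |N(0,1)| with a 70% sparsity mask
(nonnegative, sparse, THINGS-like); embeddings are constructed jointly
with a fixed linear map M so that scores = Z·M + noise holds exactly and M
is returned for oracle checks.

Default parameters (chosen once as a realistic regime): σ_shared = 0.4,
σ_group = 0.15, σ_trial = 0.8, thresholds (−2.5, −1.25, 0, 1.25, 2.5),
old_offset 1.0, new_offset −1.8; planted effects put weight 0.15 on 8 life
dimensions for the first group, 0.12 on 6 nonlife dimensions for the
second, and ±0.15 shared weights on 12 dimensions.  Under these defaults
the empirical score correlates with the true latent at r ≈ 0.91 per group
(30 + 30 observations per stimulus), cross-group r ≈ 0.6, disagreement
quadrants hold ~160 of 600 stimuli, and the residual Life model for the
first group explains R² ≈ 0.2 versus ≈ 0.1–0.16 elsewhere — magnitudes in
the range such studies report.  Embedding noise defaults to 0.25, which
yields a graded transfer profile (most dimensions r > 0.8, few > 0.9)
rather than a saturated one.

What the generator does *not* emulate: trial-order and serial-position
effects (trials are exchangeable), participant heterogeneity in response
style or criterion, reaction times, semantic structure among dimensions
(scores are independent across dimensions given the mask), and any image
content.  Passing tests therefore validate the *analysis machinery* —
scoring arithmetic, median-split logic, CV hygiene, elimination mechanics,
regression identities, recoverability of planted linear effects — not
claims about real perceptual or mnemonic processes.

The bundled dimension labels and Life/Non-life/Mixed category file
(`fixtures/dimension_categories_synthetic.tsv`) are a synthetic stand-in:
word-pair labels in the style of interpretable object-dimension sets,
categorized by whether the label relates to living things or body parts,
with ambiguous labels (e.g. *Sky/flying*) marked mixed and excluded from
modelling.

## Numerical and design choices

- One global integer seed; every stochastic consumer draws from a
  substream derived via `SeedSequence(seed, spawn_key)` with fixed keys, so
  adding consumers never perturbs existing streams.  Identical config +
  seed ⇒ byte-identical outputs (the pipeline manifest records sha256
  digests to audit this).
- Trial-noise draws do not depend on offset values, so raising
  `old_offset` under a fixed seed can only raise responses (monotonicity
  is exact, not just in expectation).
- Pearson r is defined as 0 whenever either input is constant (relevant
  for heavily penalized elastic-net folds with constant predictions).
- Grid search ties keep the first-visited point (l1_ratio-major, then
  ascending penalty); elimination ties take the lexicographically smallest
  name; smoothed-peak ties take the earlier step.  All three rules are
  deterministic and documented where they apply.
- Degenerate inputs fail loudly with named quantities: indivisible
  designs, all-zero dimensions (sparsity 1), constant residualization
  predictors, rank-deficient regression designs (collinear predictors are
  listed), windows that are even or longer than the trace.
- Problem sizes in the test suite are scaled to the smallest instances
  that still exercise the property under test (e.g. 12 + 12 participants /
  80 stimuli for pipeline round-trips; d ≤ 5, n ≤ 40 for brute-force
  equivalence), with the full 120/600/49 design used where the property is
  about the design itself.

## Known limitations

- The RFE accuracy trace's selection-induced optimism (above) is inherent
  to the specified procedure; only the first entry is an unbiased estimate.
- Top-k predictor selection and model fitting share data; reported R²
  values are optimistic for out-of-sample prediction.
- The one-tailed dimension comparisons with data-derived direction are
  exploratory; the `post_hoc_direction` flag and the optional BH
  correction exist so downstream consumers can treat them appropriately.
- With trial noise fixed at 30 + 30 observations per stimulus the
  empirical cross-group correlation is bounded by attenuation (~0.85² of
  the latent correlation); only the latent correlation reaches 1 in the
  shared-only limit.
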