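# Methods

## The measurement problem

A tau-PET scan is summarized here by 41 regional SUVR values (median
regional uptake referenced to cerebellar crus, left/right hemispheres
averaged). The clinically accepted ground truth for tau positivity is a
multi-rater visual read: positive when increased neocortical tracer uptake
appears in posterolateral temporal, occipital or parietal/precuneus
cortex; negative when there is no neocortical signal or the signal is
isolated to mesial temporal, anterolateral temporal or frontal regions.
Composite (meta-ROI) SUVRs condense a scan to one number but look only at
fixed regions; the THETA workflow instead scores a scan by what a
classifier trained on visual reads actually used, wherever it looked.

## Classifier

A two-layer stack predicts the visual rating from the 41 SUVRs.

* **Base layer** — k × r gradient-boosted tree models (LightGBM; k = 5
  folds, r = 2 repeats by default). Each repeat shuffles the training rows
  into k folds; each model trains on a fold-complement and produces
  out-of-fold predictions on its held-out fold. Defaults: 60 trees,
  15 leaves, learning rate 0.1, `feature_fraction = 0.5`. The feature
  subsampling is deliberate: regional SUVRs are strongly correlated, and
  per-tree random subspaces spread split mass across correlated regions
  instead of letting one proxy region absorb all importance — which both
  regularizes the fit and makes the downstream attributions reflect the
  full deposition pattern.
* **Stack layer** — an L2-regularized logistic model fitted on the
  out-of-fold base predictions (one averaged column per repeat). No base
  learner ever contributes a stacker input for a row it was fitted on;
  fold bookkeeping is retained in the fitted model and asserted in tests.

Splitting is stratified over the joint (visual status × concordance
group) strata: within each stratum the test share is within one
participant of the requested fraction (default 0.20), singleton strata go
to training, and remainders are assigned largest-fraction-first with
seeded tie-breaking. Prediction threshold is strict `p > 0.5`; class
imbalance is handled by stratification only. All fits are deterministic
given a seed (single-threaded, `deterministic=True`).

## Shapley attributions

Attributions target the **positive-class probability**. For panel x and
prediction function f, region i's value is its Shapley value in the game
`v(S) = E_b[f(z)]`, where z takes the panel's values on S and a reference
background row b elsewhere (interventional value-replacement; the
background is a seeded subsample, default 100 rows, of the training set).
The base value is `v(∅)`, the mean model output over the background, and
efficiency gives `base + Σφᵢ = f(x)` exactly.

* `exact_shapley` enumerates all 2^m coalitions (feasible to m = 15);
  every model evaluation is batched into one call.
* `sampled_shapley` averages marginal contributions over random feature
  orderings, drawn as antithetic pairs (each permutation also traversed
  reversed, cancelling first-order noise). The residual
  `f(x) − base − Σφ` is then spread equally over the m regions, restoring
  additivity to machine precision without changing relative rankings.
  Minimum 50 permutations; 2000 permutations track exact enumeration to
  ~1e−5 on 8-feature test models.

Because the classifier's probabilities are near-saturated for clear
cases, per-scan attribution sums land close to `1 − base` (positives) or
`−base` (negatives).

## THETA

For one scan, with attributions φ and SUVRs x over m regions:

```
Θ = Σᵢ φᵢ + Σᵢ φ̂ᵢ·xᵢ,   φ̂ᵢ = φᵢ·1[lo ≤ φᵢ ≤ hi]
```

`[lo, hi]` are the 1st and 99th percentiles (linear interpolation) of the
scan's own φ values by default (`per_scan` scope), which keeps the score
computable for a single participant; a `cohort_per_region` scope computes
the band per region across a cohort instead, and the choice is recorded
in the output. The first sum always runs over all m regions. An all-equal
φ row collapses the band onto the common value, so everything is
included; with the band opened to [0, 100] the score reduces to the
closed form `Θ = Σφᵢ(1 + xᵢ)`, which the tests verify to 1e−12.

The per-region decomposition `θᵢ = φᵢ + φ̂ᵢ·xᵢ` sums to Θ exactly. It is a
package-defined decomposition: the score itself only defines the total,
and this split attributes to each region precisely its own two terms.

Θ is reported on its natural scale (probability units plus
probability-times-SUVR units); no normalization is applied. Negatives
cluster in a narrow band near `−base·(1 + x̄)`; positives scale with both
certainty and uptake, which is what separates severity within a tau
status.

## Synthetic cohorts

The generator emulates the statistical structure the analysis needs,
not PET physics. Each participant draws a deposition archetype:

| archetype | shifted regions (SUVR above baseline) | visual | composites |
| --- | --- | --- | --- |
| negative (76%) | none | − | all − |
| mtl_predominant (5%) | entorhinal, amygdala +0.45 | − (isolated MTL) | MTL + |
| neocortical (5%) | middle/inferior temporal +0.75, superior temporal +0.30 | + | NEO +, temporal +, MTL − |
| diffuse (10%) | 22 regions; entorhinal/amygdala +0.95 strongest, temporal +0.85 | + | all + |
| focal_atypical (4%) | occipital/parietal only, +0.4–0.6 | + | all − |

Prevalences rescale so the visually positive fraction is 0.19 (a typical
population-based prevalence). Regional SUVR = baseline (mean 1.05, SD
0.08 participant-level intercept) + severity × shift + N(0, 0.05) regional
noise, floored at 0.5. The per-participant severity multiplier is
lognormal (log-SD 0.25): tau burden is a continuum, and the mild tail
produces visually positive scans whose composite SUVRs sit below cutoff —
the discordant cases composite measures miss. The diffuse pattern is
limbic-forward (entorhinal/amygdala are its largest shifts) to match the
canonical staging of tau spread. Clinical scores link to realized burden
(mean SUVR elevation): MMSE = 29 − 25·burden + N(0, 1.5) clipped to
[0, 30]; CDR-SB = 30·burden + N(0, 1) clipped to [0, 18] in half-point
steps. Diagnosis, amyloid status and APOE4 are drawn with
status-dependent prevalences. All randomness descends from one seed via
per-participant substreams, so cohorts reproduce byte-for-byte.

What the generator does **not** emulate: realistic inter-region
correlation beyond a shared intercept, within-archetype topographic
variability, rater error (labels are exact archetype properties), scanner
or site effects, and longitudinal change. Two consequences matter for
interpreting green tests. First, synthetic separability is higher than in
real cohorts, so the classifier's near-perfect recovery here says the
pipeline works, not that real-data accuracy would match. Second,
discordance here arises mostly from focality and mildness by
construction; concentration statistics of regional θ profiles depend on
that mixture, so the tests assert mixture-robust directions (e.g.
discordant scans place a larger share of |θ| outside the temporal
meta-ROI members than concordant scans) rather than a specific
concentration index.

## Evaluation statistics

* Agreement of a comparator with the visual reference: TPR = TP/(TP+FN),
  TNR = TN/(TN+FP), mismatch rates 1−TPR and 1−TNR; percentage reports
  use round-half-even at 2 decimals.
* Classification: balanced accuracy, Matthews correlation, precision,
  recall, F1, and rank-based ROC AUC with midrank tie handling
  (scikit-learn; tests cross-check against brute-force concordant-pair
  counting).
* Associations: midrank Spearman rho plus OLS slope/intercept on complete
  pairs only (missing clinical values are never imputed).
* Effect sizes: Cohen's d with the df-weighted pooled SD; two-tailed
  independent-samples t-test, pooled-variance form by default with Welch
  behind a flag, Bonferroni correction capped at 1.
* Repeatability: ICC(2,1) — two-way random effects, absolute agreement,
  single measure (pingouin; tests cross-check a hand mean-squares
  computation). Constant inputs return the value as undefined rather
  than a number.

## Validation problem sizes

The experiments behind `scripts/acceptance.py` run at desk scale, chosen
once as the package's own defaults: additivity over a fully scored
cohort of 500 (50 permutations, background 8); classifier recovery on
n = 2000 with 10 re-splits and a 10-seed shuffled-label control; ICC over
10 reruns scoring a fixed subsample of 60 participants; effect sizes on
a 250-participant subsample. At these sizes the full script completes in
a few minutes on one CPU while leaving every estimate far from its
decision boundary (e.g. sampled-vs-exact deviation ~3e−5 against a 0.01
bound).

## Numerical and design notes

* "Voxel-weighted" composite averages use configured region weights as a
  stand-in for voxel counts; the shipped default is equal weights (plain
  means), overridable per atlas. The MTL composite is unweighted by
  definition.
* All cutoff comparisons are strict-greater; a composite exactly at its
  cutoff is negative.
* Percentiles use linear interpolation between order statistics.
* Intermediate tables (cohort SUVRs, attributions) are written with 17
  significant digits and read back with round-trip float parsing, so a
  resumed pipeline reproduces a fresh run bit-for-bit; the human-facing
  score table uses 12 significant digits (≥10 digits survive a round
  trip).
* Model artifacts serialize by pickling; a reloaded ensemble reproduces
  probabilities bit-identically.
* Degenerate inputs are reported, not silently patched: a reference
  vector with no positives leaves TPR undefined; constant probability
  vectors report AUC 0.5 with a warning; zero pooled variance leaves d
  undefined.

## Limitations

* The score inherits the classifier's saturation: a visually misread
  scan would be forced toward the wrong Θ band — high sensitivity to tau
  status is both the feature and the risk.
* Exact enumeration is limited to 15 regions; full-panel attributions
  are sampling estimates whose per-region values carry O(1/√P) noise
  even though their sum is exact.
* The ensemble is a fixed small portfolio (boosted trees + logistic
  stacker), not an automated model search; no GPU, no hyperparameter
  tuning service.
* Cutoffs for the composite references are taken as configured constants;
  no data-driven re-estimation is provided, and conclusions that compare
  against composites move with those cutoffs.
* No image handling: the package starts from regional SUVR tables and
  deliberately excludes segmentation, atlas propagation and
  coregistration, as well as longitudinal modelling.
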