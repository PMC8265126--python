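# Methods

This note records the modelling assumptions, parameter choices and known
limitations of `d2tra`.  It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## The D2T definition as implemented

Only the first two criteria of the EULAR D2T RA definition are
operationalised, on structured data:

1. **Treatment failure history** — prescriptions of ≥ 2 b/tsDMARDs with
   different mechanism-of-action (MoA) classes.  Only start dates are used;
   stop dates in routine prescription systems are unreliable (refills may
   route through other prescribers) and are never parsed or generated.
   "Failing" a drug is therefore inferred purely from the start of a
   subsequent one.
2. **Active disease** — either (a) a mean DAS28-ESR ≥ 3.2 over the closed
   window [anchor + 3 months, anchor + 12 months], anchored at the start of
   the b/tsDMARD of the *second* MoA class, or (b) the start of a third
   distinct MoA class, which is itself taken as evidence of failure and
   needs no disease-activity data.

Criterion 3 (management perceived as problematic) and criterion 2c
(glucocorticoid-tapering failure) are out of scope: the former is not
recorded in structured EHR data, the latter depends on the stop dates we
exclude.

Patients for whom criterion 1 holds but neither branch of criterion 2 can
be evaluated (no DAS28 record in the window, no third MoA) are classified
**non-D2T with `data_sufficiency="insufficient"`**.  This is deliberately
conservative: incomplete records depress sensitivity but cannot create
false positives, and the monotonicity tests pin this property (deleting
records can flip D2T→non-D2T, never the reverse).

Conventions where the definition is silent: one "month" is 30.44 days
(mean Gregorian month); the activity window is closed on both ends; MoA
classes first started on the same day are ordered by the fixed taxonomy
enumeration and the tie is flagged in the evidence trail.  The window
anchor is configurable (`anchor="each_from_second"` evaluates every MoA
from the second onward) but defaults to the second-MoA start, the literal
reading of the definition.

## DAS28-ESR surrogate

Where all four components exist on one date (joint counts and VAS from the
clinical-measurements table, ESR from the labs), the score is computed
exactly.  Elsewhere a surrogate regression predicts it from the feature
classes that are broadly available: same-day laboratory values (wide),
cumulative hospital-visit count, age, sex, and the MoA-cycling pace —
defined here as (number of distinct b/tsDMARD MoA classes started) ÷
(years from first b/tsDMARD start to the patient's last recorded event),
floored at half a year to keep the ratio bounded.

The default learner is a gradient-boosted tree ensemble (400 trees, depth
4, learning rate 0.1), which consumes missing feature values natively; a
ridge linear fallback exists behind `family="linear"`.  The held-out MAE is
reported from an internal 75/25 split.  Surrogates of this kind fitted to
real routine-care data reach an MAE around 0.8 score units — for scale, the
DAS28 itself has a measurement error near 0.6 — so approximated scores are
adequate for the ≥ 3.2 window-mean decision, not for per-visit inference.
Visits with no same-day laboratory result are *not* scored (the rule engine
routes such patients through the insufficient-data path rather than
receiving a prediction unsupported by data); a nearest-date join was
rejected because it lets stale high-activity labs leak into later windows.

By default the rule engine mixes provenance: exact scores where components
exist, surrogate scores elsewhere (`das28_source="all"`).  Restricting to
one provenance is a config switch; approximated-only would leave a fully
observed patient with no usable records at all, which is why "all" is the
default.

## Letter mining

Sections are segmented by line-anchored headings (a line ending in ":" or
an all-caps line); text before the first heading lands in a synthetic
"preamble".  Medication extraction is exact-token matching (lowercased,
punctuation stripped, longest surface form first) and is scoped to the
"medication" and "DMARD history" headings — a drug merely *considered* in a
conclusion never counts.  Activity detection screens narrative headings for
a phrase list ("flare", "active arthritis", …); a match is negated when a
negation cue ("no", "not", "without", "denies") occurs within 3 tokens
before it in the same sentence.  The bounded same-sentence window is the
simplest testable contract of NegEx-style negation scoping; both the window
and the term lists are editable YAML.  The shipped English lexicon is a
synthetic stand-in co-designed with the letter templates of the generator —
real deployments need locally curated, language-appropriate lists, and no
claim about real-letter recall follows from the exact-recovery tests.

A patient is letter-classified D2T when the union of extracted medications
across all letters spans ≥ 2 MoA classes **and** at least one non-negated
activity phrase occurs.  No temporal ordering between the two kinds of
evidence is enforced; evidence is cumulative, so adding a letter can only
move a patient toward D2T.

## Feature engineering and importance

Repeated measurements are aggregated per patient with mean, median, sample
SD, mean successive difference (a trend proxy; the mean *absolute*
successive difference is a config alternative), mean − median, min and max.
SD and trend are undefined (missing) for singleton series.

The importance stack is: standard scaling → iterative imputation (each
incomplete feature regressed on the others with Bayesian Ridge, cycled to
convergence, label never used as a predictor) → univariate
Benjamini–Hochberg filtering at α = 0.05 (Welch t for continuous features,
Fisher exact for near-binary ones) → L1-penalised logistic regression over
repeated 140/12 train/test splits (1000 by default; the automated suite
uses 200).  Splits are drawn without replacement per repetition — the
reading of "bootstrapped cross-validations" adopted here — with a
with-replacement option.  The penalty strength is chosen per repetition by
3-fold cross-validation on the train part over a small grid.

The univariate screen is applied *inside* each repetition, on the train
part only.  This keeps the screen honest (it never sees the repetition's
test patients) and is load-bearing for the ranking property: with strongly
separated classes the classes become linearly separable at n = 140, and an
unscreened lasso will freely substitute a chance-correlated noise feature
for a true one, making per-feature selection frequencies meaningless.
Reported importance is the mean coefficient and the selection frequency
(screen failures count as not selected), ranked by frequency then |mean
coefficient|.  A caveat that no procedure removes: with ~40 noise features
at n ≈ 150, a noise feature can be genuinely correlated with the label *in
the realized sample*, and ranking it highly is then correct in-sample even
though it fails against the generator's ground truth.

## Identification and prediction models

Both models are XGBoost classifiers (300 trees, depth 3, learning rate 0.1,
single-threaded, hist method) evaluated with stratified 10-fold
cross-validation; missing feature values are routed natively by the trees,
so no imputation precedes them.  Reported AUC is the across-fold mean with
a normal-approximation interval (mean ± 1.96·SD/√folds); the confusion
matrix pools out-of-fold predictions and is thresholded — at 0.5 for
identification, at 0.15 for prediction, the screening-oriented operating
point that trades specificity for sensitivity.  Sensitivity/specificity are
reported rounded to whole percent, the convention of clinical validation
tables.

For prediction, each patient's record is censored strictly before the first
b/tsDMARD start (patients without one have no censor event and are
dropped), the pre-censor labs and clinical measurements are regularized to
a one-month grid by forward fill — the last observed value is carried
forward, never backward — and the grid columns are aggregated with the same
per-patient summary set, plus sex, age at censor and years from diagnosis
to censor.  A leakage test perturbing all post-censor records and asserting
a bit-identical feature matrix guards the censoring.

## Hematology embedding and Y-score

Hematology samples (one blood draw × ~20 analyzer parameters: CBC,
differential, reticulocytes, a platelet intermediate-angle-scatter proxy)
are standardized, mean-imputed and reduced to 2-D with UMAP
(n_neighbors = 15, min_dist = 0.1, fixed seed, single-threaded layout for
determinism).  Training on clinically classified patients uses supervised
UMAP with target_weight 0.6 — supervision is what strictly separates the
two training clusters, so the training-set silhouette is a property of the
method, not evidence of biology.  New cohorts are projected out-of-sample
with the fitted reducer.  Patients are summarised by the coordinate-wise
median of their sample embeddings; for cohort-level runs the per-patient
draw count is capped at 8 evenly spaced samples to bound the layout cost.

The Y-score is the unweighted mean of the available binary D2T indicators
(structured rule engine, letter miner, clinical label when present;
D2T = 1), undefined when all three are absent.  Equal weights are a choice,
not an estimate — the weighting is configurable and nothing here calibrates
it.

## Synthetic cohort generator

The generator emulates the *statistical structure* the pipeline assumes,
with planted ground truth, and is deterministic (byte-identical bundles)
under a fixed config + seed:

- **Treatment histories.** Planted D2T patients start 2–4 MoA classes
  (45/35/20%), non-D2T patients 0–1 classes (35/40%) or 2 with a responding
  trajectory (25%); TNF inhibitors lead 80% of sequences.  Gaps between
  class starts are 400–900 days.
- **Disease activity.** Latent DAS28 is piecewise-constant per treatment
  episode: pre-treatment 4.0–6.0; D2T episodes 3.8–5.5 (so the 3–12-month
  window mean after the second MoA clears 3.2 by construction); responder
  episodes 1.2–2.4 (clear of 3.2 from below).  Visit-level components are
  derived from the latent level — joint counts and VAS as deterministic
  maps plus noise scaled by `noise_sd` (default 0.3 score units), the ESR
  solved from the score equation so the four components reproduce the
  intended value, CRP a monotone transform.  At `noise_sd=0` the record
  encodes the trajectory exactly, which is what makes rule-engine recovery
  and the surrogate's MAE → 0 testable contracts.
- **Hematology.** Each parameter is patient-base + within-patient noise
  with an 85/15 between/within variance split; configured `effect_sizes`
  shift D2T patients by the stated number of total SDs (defaults 0.4–0.6 on
  leukocyte, neutrophil, platelet, hemoglobin and reticulocyte axes).  This
  variance is independent of `noise_sd`.
- **Letters.** Roughly yearly; medication sections mirror the structured
  prescription table exactly (a tested invariant).  When the latent
  trajectory is active at the letter date an activity phrase is emitted,
  negated with probability `negation_rate` (the letter-level truth then
  records *inactive* — the rendered text, not the latent state, is the
  truth the miner must recover); quiescent periods emit a negated phrase or
  a neutral sentence.  Templates are constructed to respect the miner's
  3-token negation window and sentence-boundary rule: generator and miner
  share a template contract, which is why 100% recovery is the expected
  test outcome and says nothing about free-form prose.
- **Missingness** is row-level MCAR per table, never touching the patients
  table or planted truth.  Informative missingness is a non-goal.
- **Labels.** A configurable fraction (default 0.3) of patients carries a
  tri-state clinical validation label; by default it equals the planted
  truth.

Defaults: 500 patients, D2T prevalence 0.2 (within the 5–20% range reported
for RA populations, above it only in enriched validation subsets),
diagnosis dates 2005–2015, 6–9 years of follow-up, visits every 25–45 days,
hematology draws every 90–150 days.

What the generator does **not** emulate: informative missingness, referral
effects (second-opinion patients with truncated histories), drug dosing and
stop dates, Dutch-language letters, instrument-specific research-only
hematology channels, and label noise in the clinical classification.
Passing tests therefore demonstrate internal consistency of the pipeline
under the stated assumptions, not real-world operating characteristics; the
published real-data reference points (identification AUC 0.88, prediction
AUC 0.73, surrogate MAE 0.8) are quoted in the README for scale only.

## Problem sizes and numerics

The test and acceptance runs use cohorts of 30–500 patients (up to 1000 for
the effect-size calibration check), 200 bootstrap repetitions, 300 FDR null
replicates, and 80-patient embedding fixtures — sizes chosen so each
property is measured with comfortable margins on a single CPU.  All
randomness flows from explicit seeds; XGBoost and UMAP run single-threaded
to keep results bit-reproducible.  Pipeline stage seeds derive from the
master seed by fixed offsets (stage *k* gets master + *k*), recorded in the
run manifest.  Degenerate inputs are handled explicitly: empty cohorts
classify to empty result lists, zero-visit windows route to the
insufficient-data path, singleton series leave SD/trend aggregates missing,
and all-missing feature columns are rejected rather than imputed.
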