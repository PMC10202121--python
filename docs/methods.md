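# Methods

## Model and procedure

The package corrects micronutrient biomarkers for the acute-phase response
in six stages, mirroring how the analysis is done in practice.

1. **Unit checks.** AGP must be in g/L and CRP in mg/L; the biomarker's own
   units are free (adjusted values come back in the same units). Units can
   only be checked heuristically, so a median outside a plausible range
   (AGP [0.1, 5] g/L, CRP [0.01, 200] mg/L) raises a warning, never an
   error.
2. **Summaries, LoD handling and reference deciles.** Univariate summaries
   count zeros, missing and below-LoD values. Values censored below a lower
   limit of detection (often exported as 0 or as the LoD itself) are
   replaced by a single uniform draw on the open interval (0, LoD),
   reproducible under a seed; multiple imputation is out of scope, but
   user-imputed values pass straight through. The survey's lowest decile
   (10th percentile, linear interpolation between order statistics — the
   common "type 7" definition; logged so users can audit) of each marker is
   compared with the external reference decile; if the relative difference,
   with the external value as denominator, exceeds 20%, the internal decile
   replaces the external one, per marker independently. Both the percentile
   definition and the denominator convention are interpretations — the
   underlying guidance says only "lowest decile" and "more than 20%" — and
   both are scale-consistent (a unit change never flips the decision).
3. **Direction screen.** For each marker the rule uses, a Spearman
   correlation and a log-log simple-regression slope are computed on
   complete pairs (default minimum 30). Ferritin and sTfR must relate
   positively to inflammation, retinol/RBP/zinc negatively. Adjustment is
   blocked only when every available marker contradicts the expected sign
   (or is degenerate); one consistent marker suffices. The Spearman P uses
   the large-sample t approximation (survey n is typically in the
   hundreds); an exact permutation option exists for small samples.
4. **Fit.** One joint, unweighted OLS of ln(MB) on ln(AGP) and ln(CRP)
   (raw log markers, not the truncated differences — truncation belongs to
   the correction step, not the fit), on complete cases, even when the
   survey has sampling weights. A single available marker is still used
   when the rule calls for both. Optional binary covariates (malaria
   status) enter this fit only.
5. **Truncated differences.** `max(ln(value) − ln(ref), 0)` per marker;
   equality yields 0; missing propagates.
6. **Correction.** `ln(MBadj) = ln(MBunadj) − β1·diff_AGP − β2·diff_CRP`,
   exponentiated. Rows whose total correction is zero return the input
   value *bit-exactly* (assigned, not round-tripped through exp/log). Rows
   missing any marker in the model get a missing adjusted value rather
   than a partial one-marker correction, which would silently mix
   estimands within one dataset.

Deficiency prevalence is the percentage of nonmissing values strictly
below (ferritin, retinol, RBP, zinc) or above (sTfR) a user-supplied
cutoff, optionally weighted, with a binomial standard error on request.

## Policy registry

The per-biomarker rules (which markers, expected sign, zinc's conditional
flag) and the external reference deciles are code constants exported as a
CSV (`registry.export_rules`) so tests and documentation share one source
of truth. Biomarker names are matched case-insensitively through a synonym
map; unknown names raise rather than defaulting. The zinc rule — adjust in
PSC only when Spearman r < −0.1 with P < 0.1 (two-sided; the guidance does
not specify sidedness) against either marker — is evaluated on raw values;
Spearman is rank-based, so any monotone transform gives the same answer.

MANUAL mode covers population groups without published reference deciles:
the user supplies reference values for every mapped marker, and the
group-independent rules apply (ferritin/retinol/RBP both markers, sTfR
AGP-only, folate/B-12 none). Zinc is not adjusted in MANUAL mode because
its conditional rule is established for preschool-age children only.

## Covariate (malaria) variant

`compare_with_covariate` refits the model with a binary covariate and
reports deficiency prevalence both ways. The covariate changes the fitted
inflammation slopes only; the correction never subtracts the covariate
term, and no covariate-inflammation interactions are included
(main-effects only — the simplest model answering "does including the
covariate move the estimate?").

## Synthetic data generator

`synthetic.generate_survey` draws ln(AGP), ln(CRP) from a correlated
bivariate normal and builds each biomarker from the same log-linear model
the correction assumes, plus optional Bernoulli malaria status with an
additive log-scale effect and optional LoD censoring (recorded as 0, as
raw survey exports often do). Every downstream estimate therefore has a
closed-form truth.

Defaults (chosen once as the study conditions):

* Marker distributions are calibrated so the population 10th percentile
  equals the external reference decile of the group — PSC: ln AGP ~
  N(0.177, 0.55), ln CRP ~ N(−0.508, 1.40); WRA: ln AGP ~ N(−0.039, 0.45),
  ln CRP ~ N(−0.167, 1.30) — with log-scale correlation 0.5 between the
  two markers. The sds reflect that AGP is a slow, moderate responder
  while CRP spans orders of magnitude.
* Confounding slopes follow the biology: ferritin (0.8, 0.3) — the
  ferritin-like truth also used in the recovery tests — sTfR (0.35, 0),
  retinol and RBP (−0.25, −0.08), zinc (−0.06, −0.02); log-scale noise sds
  0.6, 0.3, 0.25, 0.25, 0.18. The zinc defaults yield a Spearman r near
  −0.25 with AGP, so the conditional rule triggers under the defaults, as
  it typically does in inflamed child populations.
* Malaria prevalence and effects default to 0 (opt-in).

What the generator does **not** emulate: survey design (clusters, strata,
weights), assay error structure, age/sex structure, or non-log-linear
confounding. Passing tests show the estimator recovers a known log-linear
truth and that the decision rules behave as specified — not that any real
population satisfies the log-linear model.

## Numerical choices and problem sizes

* Percentiles: linear interpolation (pandas/numpy default), as above.
* Nonpositive values at adjustment time are a hard error (log undefined);
  imputation is the user's responsibility beforehand and is what the LoD
  step is for.
* Minimum complete cases for any fit or screen: 30, configurable.
* Test problem sizes: unit tests use n in the hundreds to a few thousand;
  calibration checks use n = 50 000; the recovery check uses 200
  replicates of n = 1000 and the null-covariate check 50 replicates of
  n = 1000 — large enough for the Monte-Carlo error to sit well inside the
  asserted bounds while the whole suite runs in seconds.

## Known limitations

* The 20% reference-decile rule and the percentile definition are
  interpretations of loosely specified guidance (documented above and in
  the QC report).
* Regression is always unweighted by design; prevalence accepts weights,
  but no design-based variance is computed.
* No rules for vitamin D or for pregnant women; no multiple imputation;
  plot-based decile inspection is replaced by numeric summaries.
* The CLI's adjusted column for a blocked or not-recommended biomarker
  repeats the unadjusted values (flagged in full mode via
  `<biomarker>_adjusted`), so downstream column arithmetic never silently
  drops participants.
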